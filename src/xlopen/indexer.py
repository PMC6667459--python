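"""Fragment-ion inverted index and intact-mass peptide index.

Every index entry is a *tetrad code*: (ion type ``t``, peptide length ``l``,
start position ``p``, modification id ``m``) packed into one 64-bit unsigned
integer with bit widths 1/7/46/10 from most- to least-significant. ``t`` = 1
for b ions, 0 for y ions. The 7-bit length field stores ``length - 1`` so
peptides of 1..128 residues are encodable; the 46-bit start position addresses
a concatenated database of up to 64 TB of residues; the 10-bit modification id
allows 1024 modified forms per peptide sequence.

Index keys are integerized masses (neutral fragment or intact-peptide mass
multiplied by 1000, rounded half away from zero). Queries run as an integer
key-range scan widened by one millidalton per side, then re-filter on the
stored real-valued mass so ppm windows are exact despite integerization.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .chemistry import WATER
from .sequence_db import ModifiedPeptide, residue_masses

T_BITS, L_BITS, P_BITS, M_BITS = 1, 7, 46, 10
L_SHIFT = P_BITS + M_BITS        # 56
T_SHIFT = L_BITS + L_SHIFT       # 63
P_SHIFT = M_BITS                 # 10
L_MAX = (1 << L_BITS) - 1        # 127 (stored value; peptide length <= 128)
P_MAX = (1 << P_BITS) - 1
M_MAX = (1 << M_BITS) - 1

ION_B = 1
ION_Y = 0


def encode_tetrad(t: int, l: int, p: int, m: int) -> int:
    """Pack raw field values into a 64-bit code. ``l`` is the stored length
    field (peptide length minus one)."""
    if not 0 <= t <= 1:
        raise ValueError(f"ion type {t} out of range [0, 1]")
    if not 0 <= l <= L_MAX:
        raise ValueError(f"length field {l} out of range [0, {L_MAX}]")
    if not 0 <= p <= P_MAX:
        raise ValueError(f"start position {p} out of range [0, {P_MAX}]")
    if not 0 <= m <= M_MAX:
        raise ValueError(f"modification id {m} out of range [0, {M_MAX}]")
    return (t << T_SHIFT) | (l << L_SHIFT) | (p << P_SHIFT) | m


def decode_tetrad(code: int) -> tuple[int, int, int, int]:
    """Unpack a 64-bit code into raw (t, l, p, m) field values."""
    code = int(code)
    if not 0 <= code < (1 << 64):
        raise ValueError("tetrad code out of 64-bit range")
    t = code >> T_SHIFT
    l = (code >> L_SHIFT) & L_MAX
    p = (code >> P_SHIFT) & P_MAX
    m = code & M_MAX
    return t, l, p, m


def mass_key(mass: float) -> int:
    """Integer index key: round-half-away-from-zero of mass x 1000."""
    return int(np.floor(mass * 1000.0 + 0.5)) if mass >= 0 else -int(np.floor(-mass * 1000.0 + 0.5))


def fragment_masses(mp: ModifiedPeptide) -> tuple[np.ndarray, np.ndarray]:
    """Neutral b/y fragment masses of a modified peptide.

    b_i = sum of the first i residue masses (modifications applied);
    y_j = sum of the last j residue masses + water. i, j = 1..L-1.
    """
    r = np.array(residue_masses(mp.sequence, mp.site_mod_dict()))
    prefix = np.cumsum(r)
    b = prefix[:-1]
    y = prefix[-1] - prefix[:-1] + WATER
    return b, y[::-1]


@dataclass
class MassIndex:
    """Sorted parallel arrays: integer keys, true masses, tetrad codes."""

    keys: np.ndarray      # int64, sorted
    masses: np.ndarray    # float64, stored real-valued masses
    codes: np.ndarray     # uint64

    def __len__(self) -> int:
        return len(self.keys)

    def query(self, query_mass: float, tol_ppm: float) -> np.ndarray:
        """All codes whose stored mass lies within query_mass * (1 +/- tol_ppm e-6)
        (closed interval)."""
        if tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")
        lo, hi = self._range(query_mass, tol_ppm)
        return self.codes[lo:hi]

    def _range(self, query_mass: float, tol_ppm: float) -> tuple[int, int]:
        delta = abs(query_mass) * tol_ppm * 1e-6
        lo_key = mass_key(query_mass - delta) - 1
        hi_key = mass_key(query_mass + delta) + 1
        lo = int(np.searchsorted(self.keys, lo_key, side="left"))
        hi = int(np.searchsorted(self.keys, hi_key, side="right"))
        m = self.masses[lo:hi]
        inside = (m >= query_mass - delta) & (m <= query_mass + delta)
        # matches are contiguous because masses are key-sorted up to 1 mDa jitter;
        # re-filter exactly with a boolean mask
        idx = np.nonzero(inside)[0]
        if idx.size == 0:
            return lo, lo
        return lo + int(idx[0]), lo + int(idx[-1]) + 1

    def query_many(self, query_masses: np.ndarray, tol_ppm: float) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized query: returns (codes, query_index) for all matches of all
        query masses, exact on the stored real-valued mass."""
        q = np.asarray(query_masses, dtype=float)
        delta = np.abs(q) * tol_ppm * 1e-6
        lo = np.searchsorted(self.masses, q - delta - 2e-3, side="left")
        hi = np.searchsorted(self.masses, q + delta + 2e-3, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.intp)
        qidx = np.repeat(np.arange(len(q)), counts)
        flat = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        m = self.masses[flat]
        keep = np.abs(m - q[qidx]) <= delta[qidx]
        return self.codes[flat[keep]], qidx[keep]


def _build(mass_list: np.ndarray, code_list: np.ndarray) -> MassIndex:
    keys = np.floor(mass_list * 1000.0 + 0.5).astype(np.int64)
    order = np.lexsort((code_list, mass_list, keys))
    return MassIndex(keys=keys[order], masses=mass_list[order], codes=code_list[order])


def build_fragment_index(mod_peptides: list[ModifiedPeptide]) -> MassIndex:
    """Index every b/y fragment of every modified peptide: 2(L-1) entries per
    peptide of length L."""
    masses: list[np.ndarray] = []
    codes: list[np.ndarray] = []
    for mp in mod_peptides:
        L = mp.length
        if L < 2 or L > L_MAX + 1:
            continue
        b, y = fragment_masses(mp)
        base_b = encode_tetrad(ION_B, L - 1, mp.peptide.start_position, mp.modification_id)
        base_y = encode_tetrad(ION_Y, L - 1, mp.peptide.start_position, mp.modification_id)
        masses.append(b)
        codes.append(np.full(len(b), base_b, dtype=np.uint64))
        masses.append(y)
        codes.append(np.full(len(y), base_y, dtype=np.uint64))
    if not masses:
        return MassIndex(np.empty(0, np.int64), np.empty(0, float), np.empty(0, np.uint64))
    return _build(np.concatenate(masses), np.concatenate(codes))


def build_peptide_index(mod_peptides: list[ModifiedPeptide]) -> MassIndex:
    """Index intact modified-peptide masses (one entry per form; ion bit 0)."""
    if not mod_peptides:
        return MassIndex(np.empty(0, np.int64), np.empty(0, float), np.empty(0, np.uint64))
    masses = np.array([mp.mono_mass for mp in mod_peptides])
    codes = np.array(
        [encode_tetrad(0, mp.length - 1, mp.peptide.start_position, mp.modification_id)
         for mp in mod_peptides],
        dtype=np.uint64,
    )
    keep = np.array([2 <= mp.length <= L_MAX + 1 for mp in mod_peptides])
    return _build(masses[keep], codes[keep])


_MAGIC = b"XLIDX001"


def save_index(index: MassIndex, path) -> None:
    """Flat binary persistence: magic header, then length-prefixed little-endian
    key/mass/code arrays. Byte-identical for identical indexes."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(index)))
        fh.write(index.keys.astype("<i8").tobytes())
        fh.write(index.masses.astype("<f8").tobytes())
        fh.write(index.codes.astype("<u8").tobytes())


def load_index(path) -> MassIndex:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != _MAGIC:
            raise ValueError(f"{path}: not an xlopen index (bad magic {magic!r})")
        (n,) = struct.unpack("<Q", fh.read(8))
        keys = np.frombuffer(fh.read(8 * n), dtype="<i8").copy()
        masses = np.frombuffer(fh.read(8 * n), dtype="<f8").copy()
        codes = np.frombuffer(fh.read(8 * n), dtype="<u8").copy()
        if len(codes) != n:
            raise ValueError(f"{path}: truncated index file")
    return MassIndex(keys=keys, masses=masses, codes=codes)
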