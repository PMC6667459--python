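"""Protein databases: FASTA loading, in-silico digestion, modified-form
enumeration, decoy generation, and monoisotopic peptide masses.

Digestion is fully specific: every peptide is bounded by enzymatic cleavage
sites (or a protein terminus) and carries its start position in the
concatenation of all protein sequences, which is what the 64-bit tetrad codes
in :mod:`xlopen.indexer` address.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from pyteomics import fasta as _pfasta

from .chemistry import AA_MASS, CANONICAL_RESIDUES, WATER, Modification

DECOY_PREFIX = "REV_"

#: Hard cap on enumerated modified forms per peptide sequence: the modification
#: identifier must fit the 10-bit tetrad field.
MAX_MOD_FORMS = 1024


@dataclass(frozen=True)
class Protein:
    identifier: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.identifier!r} has an empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.identifier!r} contains non-canonical residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class CleavageRule:
    """An enzymatic cleavage rule: cut after (C-side) or before (N-side) ``residues``,
    suppressed when the adjacent residue is in ``exceptions``."""

    name: str
    residues: frozenset[str]
    side: str = "C"             # "C": cut after site residue; "N": cut before
    exceptions: frozenset[str] = frozenset()

    def cut_positions(self, sequence: str) -> list[int]:
        """0-based positions i such that the bond between sequence[i-1] and
        sequence[i] is cleaved (excluding the termini)."""
        cuts = []
        for i in range(1, len(sequence)):
            if self.side == "C":
                if sequence[i - 1] in self.residues and sequence[i] not in self.exceptions:
                    cuts.append(i)
            else:
                if sequence[i] in self.residues and sequence[i - 1] not in self.exceptions:
                    cuts.append(i)
        return cuts


TRYPSIN = CleavageRule(name="trypsin", residues=frozenset("KR"), side="C",
                       exceptions=frozenset("P"))

ENZYMES: dict[str, CleavageRule] = {"trypsin": TRYPSIN}


@dataclass(frozen=True)
class Peptide:
    """A fully specific digestion product.

    ``start_position`` is the 0-based offset into the concatenated all-protein
    sequence; ``protein_ids`` lists every source protein in which this exact
    occurrence was found (one id per occurrence; occurrences of the same
    sequence in other proteins are separate Peptide records).
    """

    sequence: str
    start_position: int
    protein_ids: tuple[str, ...]
    missed_cleavages: int
    is_decoy: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with one resolved modification assignment.

    ``modification_id`` indexes this form among all enumerated forms of the
    peptide's *sequence* (deterministic order, < 1024). ``site_mods`` maps
    0-based residue position -> mass delta (Da).
    """

    peptide: Peptide
    modification_id: int
    site_mods: tuple[tuple[int, float], ...]
    mono_mass: float

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    @property
    def length(self) -> int:
        return self.peptide.length

    def site_mod_dict(self) -> dict[int, float]:
        return dict(self.site_mods)


def residue_masses(sequence: str, site_mods: dict[int, float] | None = None) -> list[float]:
    """Per-residue masses with site modification deltas folded in."""
    masses = [AA_MASS[aa] for aa in sequence]
    if site_mods:
        for pos, delta in site_mods.items():
            masses[pos] += delta
    return masses


def peptide_mass(sequence: str, site_mods: dict[int, float] | None = None) -> float:
    """Neutral monoisotopic mass: residue masses + mod deltas + water."""
    return sum(residue_masses(sequence, site_mods)) + WATER


def mass_of(mp: ModifiedPeptide) -> float:
    return peptide_mass(mp.sequence, mp.site_mod_dict())


def digest(protein: Protein, enzyme: CleavageRule = TRYPSIN, max_missed: int = 2,
           len_range: tuple[int, int] = (4, 100), offset: int = 0) -> list[Peptide]:
    """Fully specific digestion of one protein.

    ``offset`` is the protein's start within the concatenated database, added to
    every peptide's ``start_position``.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    lo, hi = len_range
    bounds = [0] + enzyme.cut_positions(protein.sequence) + [len(protein.sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            if not lo <= end - start <= hi:
                continue
            peptides.append(Peptide(
                sequence=protein.sequence[start:end],
                start_position=offset + start,
                protein_ids=(protein.identifier,),
                missed_cleavages=j - i - 1,
                is_decoy=protein.is_decoy,
            ))
    return peptides


def generate_decoys(proteins: list[Protein]) -> list[Protein]:
    """One decoy per target protein by full sequence reversal."""
    return [
        Protein(identifier=DECOY_PREFIX + p.identifier, sequence=p.sequence[::-1],
                is_decoy=True)
        for p in proteins
    ]


def enumerate_modified_forms(peptide: Peptide,
                             fixed_mods: list[Modification] = (),
                             variable_mods: list[Modification] = (),
                             max_var: int = 3) -> list[ModifiedPeptide]:
    """Enumerate modification assignments for one peptide.

    Fixed modifications are applied unconditionally at every eligible site.
    Variable modifications are enumerated over all eligible-site subsets with
    at most ``max_var`` total, in a deterministic order (fewest variable mods
    first, then by site positions), so the form with modification_id 0 is
    always the fixed-mods-only form. At most 1024 forms are retained.
    """
    if max_var < 0:
        raise ValueError("max_var must be >= 0")
    seq = peptide.sequence
    base: dict[int, float] = {}
    for mod in fixed_mods:
        sites = [i for i, aa in enumerate(seq) if aa in mod.targets]
        for i in sites:
            base[i] = base.get(i, 0.0) + mod.delta

    # eligible (position, delta) choices for variable mods; a site carries at
    # most one variable mod
    var_sites: list[tuple[int, float]] = []
    for mod in variable_mods:
        for i, aa in enumerate(seq):
            if aa in mod.targets:
                var_sites.append((i, mod.delta))
    var_sites.sort()

    forms: list[ModifiedPeptide] = []
    mod_id = 0
    for k in range(0, max_var + 1):
        if mod_id >= MAX_MOD_FORMS:
            break
        for combo in itertools.combinations(var_sites, k):
            positions = [pos for pos, _ in combo]
            if len(set(positions)) != len(positions):
                continue
            site_mods = dict(base)
            for pos, delta in combo:
                site_mods[pos] = site_mods.get(pos, 0.0) + delta
            forms.append(ModifiedPeptide(
                peptide=peptide,
                modification_id=mod_id,
                site_mods=tuple(sorted(site_mods.items())),
                mono_mass=peptide_mass(seq, site_mods),
            ))
            mod_id += 1
            if mod_id >= MAX_MOD_FORMS:
                break
    return forms


def read_fasta(path) -> list[Protein]:
    """Read a protein FASTA; the identifier is the description up to the first
    whitespace. Decoy status is inferred from the decoy prefix."""
    proteins = []
    with _pfasta.read(str(path)) as reader:
        for description, sequence in reader:
            identifier = description.split()[0]
            proteins.append(Protein(
                identifier=identifier,
                sequence=sequence.upper(),
                is_decoy=identifier.startswith(DECOY_PREFIX),
            ))
    return proteins


def write_fasta(proteins: list[Protein], path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.identifier}\n{p.sequence}\n")


@dataclass
class PeptideDatabase:
    """The digested target+decoy database behind the indexes.

    Holds the concatenated sequence (which tetrad start positions address),
    every peptide occurrence, the per-sequence modified-form table used to
    resolve modification identifiers, and a sequence -> protein-id map used
    for intra/inter grouping and target/decoy labelling.
    """

    proteins: list[Protein]
    concatenated: str
    peptides: list[Peptide]
    mod_forms: dict[str, list[tuple[tuple[int, float], ...]]]
    seq_proteins: dict[str, frozenset[str]]

    def form_site_mods(self, sequence: str, modification_id: int) -> dict[int, float]:
        return dict(self.mod_forms[sequence][modification_id])

    def sequence_at(self, start: int, length: int) -> str:
        return self.concatenated[start:start + length]


def build_database(targets: list[Protein],
                   enzyme: CleavageRule = TRYPSIN,
                   max_missed: int = 2,
                   len_range: tuple[int, int] = (4, 100),
                   fixed_mods: list[Modification] = (),
                   variable_mods: list[Modification] = (),
                   max_var: int = 3,
                   add_decoys: bool = True) -> tuple[PeptideDatabase, list[ModifiedPeptide]]:
    """Digest targets (+ reversed decoys), enumerate modified forms, and return
    the database together with the flat list of all modified peptides."""
    proteins = list(targets)
    if add_decoys:
        proteins += generate_decoys(targets)

    concatenated_parts: list[str] = []
    peptides: list[Peptide] = []
    offset = 0
    for prot in proteins:
        concatenated_parts.append(prot.sequence)
        peptides.extend(digest(prot, enzyme, max_missed, len_range, offset=offset))
        offset += len(prot.sequence)

    mod_forms: dict[str, list[tuple[tuple[int, float], ...]]] = {}
    seq_proteins: dict[str, set[str]] = {}
    all_forms: list[ModifiedPeptide] = []
    for pep in peptides:
        seq_proteins.setdefault(pep.sequence, set()).update(pep.protein_ids)
        if pep.sequence not in mod_forms:
            forms = enumerate_modified_forms(pep, fixed_mods, variable_mods, max_var)
            mod_forms[pep.sequence] = [f.site_mods for f in forms]
            all_forms.extend(forms)
        else:
            # same sequence seen at another locus: same form table, new occurrence
            for mid, site_mods in enumerate(mod_forms[pep.sequence]):
                all_forms.append(ModifiedPeptide(
                    peptide=pep, modification_id=mid, site_mods=site_mods,
                    mono_mass=peptide_mass(pep.sequence, dict(site_mods)),
                ))

    db = PeptideDatabase(
        proteins=proteins,
        concatenated="".join(concatenated_parts),
        peptides=peptides,
        mod_forms=mod_forms,
        seq_proteins={s: frozenset(ids) for s, ids in seq_proteins.items()},
    )
    return db, all_forms
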