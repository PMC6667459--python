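"""File I/O and configuration: MGF spectra, TOML search configs, TSV reports.

Coordinate conventions: peptide-internal link sites are 1-based in every file
written or read here; the 0-based start positions inside tetrad codes are an
internal contract of the indexer and never appear in reports.
"""
from __future__ import annotations

import sys
import tomllib
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from pyteomics import mgf as _pmgf

from .chemistry import LINKERS, MODIFICATIONS, PROTON, LinkerSpec, Modification
from .search import Spectrum
from .sequence_db import ENZYMES, CleavageRule, TRYPSIN


@dataclass
class SearchConfig:
    enzyme: str = "trypsin"
    max_missed: int = 2
    fixed_mods: list[str] = field(default_factory=list)
    variable_mods: list[str] = field(default_factory=list)
    max_var: int = 3
    linker: str = "BS3"
    precursor_tol_ppm: float = 20.0
    fragment_tol_ppm: float = 20.0
    fdr_threshold: float = 0.05
    fdr_mode: str = "separate"
    min_len: int = 4
    max_len: int = 100
    top_k: int = 5
    default_charges: list[int] = field(default_factory=lambda: [2, 3])

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be > 0")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError(f"fdr_threshold must be in (0, 1], got {self.fdr_threshold}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.fdr_mode not in ("separate", "global"):
            raise ValueError(f"fdr_mode must be 'separate' or 'global', got {self.fdr_mode!r}")
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.linker not in LINKERS:
            raise ValueError(f"unknown linker {self.linker!r}")
        for m in list(self.fixed_mods) + list(self.variable_mods):
            if m not in MODIFICATIONS:
                raise ValueError(f"unknown modification {m!r}")

    @property
    def enzyme_rule(self) -> CleavageRule:
        return ENZYMES[self.enzyme]

    @property
    def linker_spec(self) -> LinkerSpec:
        return LINKERS[self.linker]

    @property
    def fixed_mod_specs(self) -> list[Modification]:
        return [MODIFICATIONS[m] for m in self.fixed_mods]

    @property
    def variable_mod_specs(self) -> list[Modification]:
        return [MODIFICATIONS[m] for m in self.variable_mods]

    @property
    def len_range(self) -> tuple[int, int]:
        return (self.min_len, self.max_len)


def load_config(path) -> SearchConfig:
    """Load a TOML search configuration; unknown keys are rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in fields(SearchConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SearchConfig(**data)


def neutral_mass(pepmass: float, charge: int) -> float:
    """Neutral monoisotopic mass from an observed m/z and charge."""
    return pepmass * charge - charge * PROTON


def read_mgf(path, default_charges: list[int] | None = None) -> list[Spectrum]:
    """Read centroided MS2 spectra from a mascot generic format file.

    Spectra without a CHARGE line are interpreted at the first configured
    default charge. Empty-peak blocks are skipped with a warning to stderr.
    """
    default_charges = default_charges or [2]
    spectra = []
    with _pmgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            title = str(params.get("title", f"scan_{len(spectra)}"))
            if len(entry["m/z array"]) == 0:
                print(f"warning: skipping empty-peak spectrum {title!r}", file=sys.stderr)
                continue
            pepmass = params["pepmass"][0]
            charges = params.get("charge")
            charge = int(charges[0]) if charges else default_charges[0]
            spectra.append(Spectrum(
                title=title,
                precursor_mass=neutral_mass(pepmass, charge),
                precursor_charge=charge,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
            ))
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    """Deterministic, byte-stable MGF writer (fixed 6/2 decimal formatting)."""
    with open(path, "w") as fh:
        for s in spectra:
            mz = (s.precursor_mass + s.precursor_charge * PROTON) / s.precursor_charge
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.title}\n")
            fh.write(f"PEPMASS={mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{m:.6f} {i:.2f}\n")
            fh.write("END IONS\n")


def write_results(table: pd.DataFrame, path) -> None:
    """Stable, UTF-8, tab-separated report with one header row."""
    table.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=[], dtype={"spectrum": str})
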