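"""Monoisotopic mass constants, modifications, and cross-linker definitions.

Residue masses come from the standard monoisotopic table (via :mod:`pyteomics.mass`).
All masses are neutral monoisotopic daltons unless stated otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

#: Monoisotopic residue masses for the 20 canonical amino acids.
AA_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

CANONICAL_RESIDUES = frozenset(AA_MASS)

WATER = _pmass.calculate_mass(formula="H2O")    # 18.0105646863...
PROTON = _pmass.nist_mass["H+"][0][0]           # 1.00727646677


@dataclass(frozen=True)
class Modification:
    """A fixed or variable post-translational modification.

    ``targets`` is the set of residue letters the modification may occupy.
    """

    name: str
    delta: float
    targets: frozenset[str]

    def __post_init__(self) -> None:
        bad = set(self.targets) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"modification {self.name!r} targets unknown residues {sorted(bad)}")


def modification(name: str, delta: float, targets: str) -> Modification:
    return Modification(name=name, delta=delta, targets=frozenset(targets))


#: Common modifications, addressable by name in configs.
MODIFICATIONS: dict[str, Modification] = {
    "carbamidomethyl": modification("carbamidomethyl", 57.021464, "C"),
    "oxidation": modification("oxidation", 15.994915, "M"),
}


@dataclass(frozen=True)
class LinkerSpec:
    """A cross-linker: the mass it adds between two peptides and where it attaches.

    ``xl_mass`` is the neutral mass added by an intact cross-link (or loop-link);
    ``mono_mass_delta`` is the mass of a hydrolyzed/dead-end (mono) link on a single
    peptide. ``site_alpha``/``site_beta`` are the linkable residue sets for the two
    ends; ``protein_nterm`` additionally allows the protein N-terminal amine.
    """

    name: str
    xl_mass: float
    mono_mass_delta: float
    site_alpha: frozenset[str]
    site_beta: frozenset[str]
    protein_nterm: bool = False

    def __post_init__(self) -> None:
        if not self.site_alpha or not self.site_beta:
            raise ValueError("linkable residue sets must be non-empty")


#: Shipped linker library. Masses are standard chemistry: BS3 adds C8H10O2 between
#: two primary amines; a hydrolyzed BS3 mono-link adds C8H12O3; a disulfide bond
#: removes two hydrogens between cysteines (no dead-end form).
LINKERS: dict[str, LinkerSpec] = {
    "BS3": LinkerSpec(
        name="BS3",
        xl_mass=138.068074,
        mono_mass_delta=156.078644,
        site_alpha=frozenset("K"),
        site_beta=frozenset("K"),
        protein_nterm=True,
    ),
    "SS": LinkerSpec(
        name="SS",
        xl_mass=-2.015650,
        mono_mass_delta=0.0,
        site_alpha=frozenset("C"),
        site_beta=frozenset("C"),
    ),
}


def get_linker(name: str) -> LinkerSpec:
    try:
        return LINKERS[name]
    except KeyError:
        raise KeyError(f"unknown linker {name!r}; shipped linkers: {sorted(LINKERS)}") from None
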