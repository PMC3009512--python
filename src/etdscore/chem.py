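"""Monoisotopic peptide chemistry and theoretical ETD fragment ions.

Masses are monoisotopic throughout (the norm for Orbitrap-class data).
Residue masses are loaded from a plain-text table shipped with the
package; fixed carbamidomethylation of cysteine (+57.02146 Da) is on by
default, matching tryptic digests alkylated with iodoacetamide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PROTON",
    "H",
    "H2O",
    "NH3",
    "CO",
    "RESIDUE_MASSES",
    "DEFAULT_FIXED_MODS",
    "AVERAGE_RESIDUE_MASS",
    "Peptide",
    "IonType",
    "TheoreticalIon",
    "ION_TYPES",
    "SCORED_ION_TYPE_NAMES",
    "scored_ion_types",
    "peptide_mass",
    "fragment_ions",
    "estimate_peptide_size",
]

# Fundamental monoisotopic constants (Da)
PROTON = 1.007276
H = 1.007825
H2O = 18.010565
NH3 = 17.026549
CO = 27.994915

#: Average amino-acid residue mass used for quick peptide-size estimates.
AVERAGE_RESIDUE_MASS = 112.0


def _load_residue_masses() -> dict[str, float]:
    table = {}
    text = resources.files(__package__).joinpath("residues.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, mass = line.split("\t")
        table[code] = float(mass)
    return table


RESIDUE_MASSES: Mapping[str, float] = _load_residue_masses()

#: Carbamidomethylation of cysteine, the only fixed modification supported.
DEFAULT_FIXED_MODS: Mapping[str, float] = {"C": 57.02146}


@dataclass(frozen=True)
class Peptide:
    """A peptide: an ordered string of one-letter residue codes.

    Parameters
    ----------
    sequence:
        One-letter codes of the 20 standard residues, length >= 2.
    fixed_mods:
        Residue code -> mass delta (Da) applied to every occurrence.
        Defaults to carbamidomethyl-C.
    """

    sequence: str
    fixed_mods: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FIXED_MODS))

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError(f"peptide must have length >= 2, got {self.sequence!r}")
        for code in self.sequence:
            if code not in RESIDUE_MASSES:
                raise ValueError(f"unknown residue code {code!r} in {self.sequence!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_masses(self) -> list[float]:
        """Per-residue masses including fixed modifications."""
        return [
            RESIDUE_MASSES[c] + self.fixed_mods.get(c, 0.0) for c in self.sequence
        ]


@dataclass(frozen=True)
class IonType:
    """An ETD fragment ion series.

    ``neutral_offset`` is added to the fragment's residue-mass sum to get
    the fragment neutral mass; m/z = (neutral + charge * proton) / charge.
    """

    name: str
    terminus: str  # "N" or "C"
    neutral_offset: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.terminus not in ("N", "C"):
            raise ValueError(f"terminus must be N or C, got {self.terminus!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    def mz(self, residue_sum: float) -> float:
        return (residue_sum + self.neutral_offset + self.charge * PROTON) / self.charge


# Neutral-mass offsets relative to the fragment residue-mass sum:
#   b: 0 (so b m/z = prefix + proton), a = b - CO, c = b + NH3
#   y: +H2O, z = y - NH3, z' = z + H (z ion with an additional hydrogen)
_Z_OFFSET = H2O - NH3
_ZP_OFFSET = _Z_OFFSET + H

#: All twelve ion types with measurable frequency in ETD training data.
ION_TYPES: Mapping[str, IonType] = {
    t.name: t
    for t in (
        IonType("z'", "C", _ZP_OFFSET),
        IonType("c", "N", NH3),
        IonType("y", "C", H2O),
        IonType("z", "C", _Z_OFFSET),
        IonType("b", "N", 0.0),
        IonType("a", "N", -CO),
        IonType("z'2+", "C", _ZP_OFFSET, charge=2),
        IonType("y-H2O", "C", 0.0),
        IonType("c-H2O", "N", NH3 - H2O),
        IonType("z'-NH3", "C", _ZP_OFFSET - NH3),
        IonType("a-NH3", "N", -CO - NH3),
        IonType("b-H2O", "N", -H2O),
    )
}

#: The eight most frequent types used by the score function (z excluded:
#: it is nearly redundant with z').
SCORED_ION_TYPE_NAMES: tuple[str, ...] = (
    "z'",
    "c",
    "y",
    "b",
    "a",
    "y-H2O",
    "c-H2O",
    "z'2+",
)


def scored_ion_types() -> list[IonType]:
    return [ION_TYPES[n] for n in SCORED_ION_TYPE_NAMES]


@dataclass(frozen=True)
class TheoreticalIon:
    """A predicted fragment ion of a peptide at fragmentation site ``site``.

    Sites are numbered 1..n-1 from the N-terminus; an N-terminal ion at
    site j contains residues 1..j, a C-terminal ion residues j+1..n.
    """

    ion_type: IonType
    site: int
    mz: float


def peptide_mass(p: Peptide) -> float:
    """Monoisotopic neutral mass of the peptide (residues + mods + H2O)."""
    return sum(p.residue_masses()) + H2O


def fragment_ions(p: Peptide, types: Iterable[IonType]) -> list[TheoreticalIon]:
    """Theoretical fragment ions of ``p`` for the given ion types.

    Returns (n-1) * len(types) ions, ordered by type then site.
    """
    n = len(p)
    if n < 2:
        raise ValueError("peptide must have length >= 2")
    masses = p.residue_masses()
    prefix = [0.0]
    for m in masses:
        prefix.append(prefix[-1] + m)
    total = prefix[-1]
    ions = []
    for t in types:
        for j in range(1, n):
            residue_sum = prefix[j] if t.terminus == "N" else total - prefix[j]
            ions.append(TheoreticalIon(t, j, t.mz(residue_sum)))
    return ions


def estimate_peptide_size(precursor_mass: float) -> float:
    """Estimated residue count: precursor neutral mass / 112 Da (unrounded)."""
    if precursor_mass <= 0:
        raise ValueError(f"precursor mass must be positive, got {precursor_mass}")
    return precursor_mass / AVERAGE_RESIDUE_MASS
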