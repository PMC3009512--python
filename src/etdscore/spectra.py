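"""Spectrum container, MGF reading/writing and precursor-peak removal.

Intensities feed the score only through ranks and ratios, so no
normalization is applied on read. MGF is the canonical format; peaks are
kept as parallel numpy arrays sorted by m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .chem import H2O, NH3, PROTON

__all__ = [
    "Peak",
    "Spectrum",
    "read_mgf",
    "write_mgf",
    "remove_precursor_peaks",
]

#: Default half-window (Da) around each precursor-derived m/z to strip.
DEFAULT_PRECURSOR_TOL = 2.0


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum with precursor metadata.

    Peaks are stored as parallel arrays and sorted ascending by m/z on
    construction.
    """

    id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    precursor_charge: int

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(~np.isfinite(self.mz)) or np.any(~np.isfinite(self.intensity)):
            raise ValueError(f"spectrum {self.id}: non-finite peak values")
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise ValueError(f"spectrum {self.id}: invalid peak values")
        if self.precursor_charge < 1:
            raise ValueError(f"spectrum {self.id}: charge must be >= 1")
        if self.precursor_neutral_mass <= 0:
            raise ValueError(f"spectrum {self.id}: non-positive precursor mass")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def precursor_neutral_mass(self) -> float:
        z = self.precursor_charge
        return self.precursor_mz * z - z * PROTON

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]


def read_mgf(path) -> list[Spectrum]:
    """Parse a Mascot Generic Format file into spectra.

    Raises ``ValueError`` naming the block index when PEPMASS is missing
    and the line number for unparseable peak lines.
    """
    spectra: list[Spectrum] = []
    in_block = False
    block_index = -1
    title = None
    pepmass = None
    charge = None
    mzs: list[float] = []
    ints: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                in_block = True
                block_index += 1
                title, pepmass, charge = None, None, None
                mzs, ints = [], []
            elif line == "END IONS":
                if pepmass is None:
                    raise ValueError(
                        f"MGF block {block_index}: missing PEPMASS"
                    )
                spectra.append(
                    Spectrum(
                        id=title if title is not None else f"index={block_index}",
                        mz=np.array(mzs),
                        intensity=np.array(ints),
                        precursor_mz=pepmass,
                        precursor_charge=charge if charge is not None else 1,
                    )
                )
                in_block = False
            elif in_block:
                if line.startswith("TITLE="):
                    title = line[len("TITLE=") :]
                elif line.startswith("PEPMASS="):
                    pepmass = float(line[len("PEPMASS=") :].split()[0])
                elif line.startswith("CHARGE="):
                    charge = int(line[len("CHARGE=") :].rstrip("+"))
                elif "=" in line and not line[0].isdigit():
                    continue  # unknown header key
                else:
                    parts = line.split()
                    if len(parts) < 2:
                        raise ValueError(f"line {lineno}: unparseable peak line {line!r}")
                    try:
                        mzs.append(float(parts[0]))
                        ints.append(float(parts[1]))
                    except ValueError as exc:
                        raise ValueError(
                            f"line {lineno}: unparseable peak line {line!r}"
                        ) from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra as MGF; round-trip safe to 6 significant digits."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{m:.5f} {i:.6g}\n")
            fh.write("END IONS\n")


def remove_precursor_peaks(s: Spectrum, tol: float = DEFAULT_PRECURSOR_TOL) -> Spectrum:
    """Strip residual precursor peaks (all charge states 1..z, plus their
    H2O / NH3 neutral-loss satellites) within ``tol`` Da.

    Idempotent; never adds peaks.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    M = s.precursor_neutral_mass
    targets = []
    for c in range(1, s.precursor_charge + 1):
        base = (M + c * PROTON) / c
        targets.extend((base, base - H2O / c, base - NH3 / c))
    keep = np.ones(len(s), dtype=bool)
    for t in targets:
        keep &= np.abs(s.mz - t) > tol
    return Spectrum(
        id=s.id,
        mz=s.mz[keep],
        intensity=s.intensity[keep],
        precursor_mz=s.precursor_mz,
        precursor_charge=s.precursor_charge,
    )
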