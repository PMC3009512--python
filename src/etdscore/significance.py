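"""Peak significance level: four rank/ratio features and their combination.

The significance level replaces raw intensity as the signal/noise
discriminator. It is a linear combination of the natural logs of four
features — adjusted global rank, local rank, global intensity ratio and
local intensity ratio — each floored at 1 so every log term is >= 0.
Smaller means more significant; the strongest peak of any spectrum gets
exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .chem import estimate_peptide_size
from .spectra import Spectrum

__all__ = [
    "LOCAL_WINDOW",
    "RATIO_CAP",
    "PeakFeatures",
    "SignificanceModel",
    "PUBLISHED_COEFFICIENTS",
    "global_rank",
    "adjusted_global_rank",
    "global_reference_intensity",
    "global_intensity_ratio",
    "local_rank",
    "local_intensity_ratio",
    "peak_features",
    "spectrum_features",
    "significance_level",
    "spectrum_significance_levels",
]

#: Local-window half-width (Da): the mass of the smallest residue (Gly),
#: rounded to an integer.
LOCAL_WINDOW = 57.0

#: Cap applied to intensity ratios when the current peak has intensity 0.
RATIO_CAP = 1e6


class PeakFeatures(NamedTuple):
    """The four significance features of one peak; all >= 1."""

    r_g: float  # adjusted global rank
    r_l: float  # local rank
    t_g: float  # global intensity ratio
    t_l: float  # local intensity ratio


@dataclass(frozen=True)
class SignificanceModel:
    """Nonnegative coefficients combining the four log-features."""

    c_rg: float = 0.22
    c_rl: float = 0.40
    c_tg: float = 0.05
    c_tl: float = 0.33

    def __post_init__(self) -> None:
        if min(self.c_rg, self.c_rl, self.c_tg, self.c_tl) < 0:
            raise ValueError("coefficients must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.c_rg, self.c_rl, self.c_tg, self.c_tl])

    def normalized(self) -> "SignificanceModel":
        total = self.c_rg + self.c_rl + self.c_tg + self.c_tl
        if total <= 0:
            raise ValueError("at least one coefficient must be positive")
        return SignificanceModel(
            self.c_rg / total, self.c_rl / total, self.c_tg / total, self.c_tl / total
        )


#: Coefficients trained on the original 130-pair ETD set; the shipped default.
PUBLISHED_COEFFICIENTS = SignificanceModel(0.22, 0.40, 0.05, 0.33)


def global_rank(s: Spectrum, peak_index: int) -> int:
    """Number of peaks at least as high as the queried one (itself included)."""
    if len(s) == 0:
        raise ValueError("empty spectrum")
    return int(np.count_nonzero(s.intensity >= s.intensity[peak_index]))


def adjusted_global_rank(s: Spectrum, peak_index: int) -> float:
    """Global rank divided by the estimated peptide size, floored at 1.

    The floor preserves the convention that the strongest peak scores
    exactly 0 regardless of peptide size.
    """
    size = estimate_peptide_size(s.precursor_neutral_mass)
    return max(1.0, global_rank(s, peak_index) / size)


def global_reference_intensity(s: Spectrum, choice: str = "c") -> float:
    """Reference intensity for the intensity-ratio features.

    choice 'a': highest peak; 'b': second highest; 'c' (default): mean of
    the 3rd..10th highest. With fewer than 10 peaks choice 'c' averages
    the 3rd..last; with fewer than 3 it returns the lowest intensity.
    """
    if len(s) == 0:
        raise ValueError("empty spectrum")
    desc = np.sort(s.intensity)[::-1]
    if choice == "a":
        return float(desc[0])
    if choice == "b":
        return float(desc[min(1, len(desc) - 1)])
    if choice == "c":
        if len(desc) < 3:
            return float(desc[-1])
        return float(desc[2:10].mean())
    raise ValueError(f"unknown reference choice {choice!r}")


def _ratio(reference: float, h: float) -> float:
    if h <= 0:
        return RATIO_CAP
    return min(RATIO_CAP, max(1.0, reference / h))


def global_intensity_ratio(s: Spectrum, peak_index: int, choice: str = "c") -> float:
    return _ratio(global_reference_intensity(s, choice), s.intensity[peak_index])


def _window(s: Spectrum, peak_index: int, half_width: float) -> slice:
    lo = int(np.searchsorted(s.mz, s.mz[peak_index] - half_width, side="left"))
    hi = int(np.searchsorted(s.mz, s.mz[peak_index] + half_width, side="right"))
    return slice(lo, hi)


def local_rank(s: Spectrum, peak_index: int, half_width: float = LOCAL_WINDOW) -> int:
    """Rank of the peak among peaks within +/- ``half_width`` Da (inclusive)."""
    w = s.intensity[_window(s, peak_index, half_width)]
    return int(np.count_nonzero(w >= s.intensity[peak_index]))


def local_intensity_ratio(
    s: Spectrum, peak_index: int, choice: str = "c", half_width: float = LOCAL_WINDOW
) -> float:
    """max(1, min(h1, h2) / h) with h1 the window maximum and h2 the
    global reference intensity."""
    h1 = float(s.intensity[_window(s, peak_index, half_width)].max())
    h2 = global_reference_intensity(s, choice)
    return _ratio(min(h1, h2), s.intensity[peak_index])


def peak_features(
    s: Spectrum, peak_index: int, choice: str = "c", half_width: float = LOCAL_WINDOW
) -> PeakFeatures:
    return PeakFeatures(
        adjusted_global_rank(s, peak_index),
        local_rank(s, peak_index, half_width),
        global_intensity_ratio(s, peak_index, choice),
        local_intensity_ratio(s, peak_index, choice, half_width),
    )


def spectrum_features(
    s: Spectrum, choice: str = "c", half_width: float = LOCAL_WINDOW
) -> np.ndarray:
    """Features of every peak of ``s`` as an (n_peaks, 4) array.

    Column order matches :class:`PeakFeatures`. Vectorized equivalent of
    calling :func:`peak_features` per peak.
    """
    n = len(s)
    if n == 0:
        raise ValueError("empty spectrum")
    intens = s.intensity
    asc = np.sort(intens)
    # count of intensities >= own = n - (count strictly below)
    rg = n - np.searchsorted(asc, intens, side="left")
    size = estimate_peptide_size(s.precursor_neutral_mass)
    rg_adj = np.maximum(1.0, rg / size)

    ref = global_reference_intensity(s, choice)
    with np.errstate(divide="ignore"):
        tg = np.where(intens > 0, ref / intens, np.inf)
    tg = np.clip(tg, 1.0, RATIO_CAP)

    lo = np.searchsorted(s.mz, s.mz - half_width, side="left")
    hi = np.searchsorted(s.mz, s.mz + half_width, side="right")
    rl = np.empty(n)
    h1 = np.empty(n)
    for i in range(n):
        w = intens[lo[i] : hi[i]]
        rl[i] = np.count_nonzero(w >= intens[i])
        h1[i] = w.max()
    with np.errstate(divide="ignore"):
        tl = np.where(intens > 0, np.minimum(h1, ref) / intens, np.inf)
    tl = np.clip(tl, 1.0, RATIO_CAP)
    return np.column_stack([rg_adj, rl, tg, tl])


def significance_level(features: PeakFeatures, model: SignificanceModel) -> float:
    """c_rg*ln(r_g) + c_rl*ln(r_l) + c_tg*ln(t_g) + c_tl*ln(t_l).

    Smaller is more significant; a peak with all features 1 (the
    spectrum's strongest) scores exactly 0.
    """
    if min(features) < 1:
        raise ValueError(f"all features must be >= 1, got {features}")
    return (
        model.c_rg * math.log(features.r_g)
        + model.c_rl * math.log(features.r_l)
        + model.c_tg * math.log(features.t_g)
        + model.c_tl * math.log(features.t_l)
    )


def spectrum_significance_levels(
    s: Spectrum,
    model: SignificanceModel,
    choice: str = "c",
    half_width: float = LOCAL_WINDOW,
) -> np.ndarray:
    """Significance level of every peak of ``s`` (vectorized)."""
    feats = spectrum_features(s, choice, half_width)
    return np.log(feats) @ model.as_array()
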