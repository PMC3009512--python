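"""Training of the significance coefficients and the per-ion-type
likelihood-ratio functions f(x).

Coefficients are found by exhaustive grid search maximizing the ROC AUC
for separating real fragment-ion matches (signal) from random-m/z decoy
matches. The per-(ion type, position class) functions f are trained by
splitting the matched signal levels into four equal-count intervals and
taking the log likelihood ratio of signal vs decoy mass in each.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .chem import ION_TYPES, IonType, Peptide, fragment_ions
from .significance import (
    LOCAL_WINDOW,
    PeakFeatures,
    SignificanceModel,
    spectrum_features,
)
from .spectra import Spectrum

__all__ = [
    "DEFAULT_FRAGMENT_TOL",
    "DEFAULT_DECOY_MULTIPLIER",
    "POSITION_CLASSES",
    "position_class",
    "LabeledLevel",
    "TrainingPair",
    "IonScoreFunction",
    "nearest_peak",
    "collect_signal_levels",
    "collect_decoy_levels",
    "roc_auc",
    "grid_search_coefficients",
    "train_ion_score_function",
    "evaluate_f",
]

logger = logging.getLogger("etdscore")

#: Fragment-mass matching tolerance (Da); the original search setting.
DEFAULT_FRAGMENT_TOL = 0.8
#: Decoy draws per signal ion.
DEFAULT_DECOY_MULTIPLIER = 10
#: Minimum matched signal records to train a position-specific f; below
#: this the position class falls back to the type's pooled function.
MIN_MATCHED_RECORDS = 40

#: Position classes for the five f functions per ion type.
POSITION_CLASSES = ("N1", "N2", "MID", "C2", "C1")


def position_class(site: int, n: int) -> str:
    """Class of fragmentation site ``site`` (1..n-1) of an n-residue peptide.

    First/second site from the N-terminus, last/second-last from the
    C-terminus, middle otherwise. For short peptides a site claimed by
    several classes goes to the earliest of N1, C1, N2, C2.
    """
    if not 1 <= site <= n - 1:
        raise ValueError(f"site {site} out of range for length {n}")
    if site == 1:
        return "N1"
    if site == n - 1:
        return "C1"
    if site == 2:
        return "N2"
    if site == n - 2:
        return "C2"
    return "MID"


@dataclass(frozen=True)
class LabeledLevel:
    """One observed ion/decoy match: its significance level (None = no
    matching peak) and provenance."""

    level: float | None
    label: str  # "signal" | "decoy"
    ion_type: str | None = None
    position_class: str | None = None
    features: PeakFeatures | None = None

    @property
    def matched(self) -> bool:
        return self.level is not None


@dataclass(frozen=True)
class TrainingPair:
    spectrum_id: str
    peptide: Peptide


def nearest_peak(s: Spectrum, mz: float, tol: float) -> int | None:
    """Index of the peak nearest to ``mz`` within ``tol`` Da, or None.

    Distance ties are broken toward the higher-intensity peak.
    """
    i = int(np.searchsorted(s.mz, mz))
    best = None
    best_d = np.inf
    for j in (i - 1, i):
        if not 0 <= j < len(s):
            continue
        d = abs(s.mz[j] - mz)
        if d > tol:
            continue
        if (
            best is None
            or d < best_d - 1e-12
            or (abs(d - best_d) <= 1e-12 and s.intensity[j] > s.intensity[best])
        ):
            best, best_d = j, d
    return best


def _match_many(s: Spectrum, mzs: np.ndarray, tol: float) -> np.ndarray:
    """Vectorized nearest-within-tol matching; -1 marks no match."""
    if len(s) == 0:
        return np.full(len(mzs), -1)
    idx = np.searchsorted(s.mz, mzs)
    left = np.clip(idx - 1, 0, len(s) - 1)
    right = np.clip(idx, 0, len(s) - 1)
    dl = np.abs(s.mz[left] - mzs)
    dr = np.abs(s.mz[right] - mzs)
    tie = np.abs(dl - dr) <= 1e-12
    pick_left = (dl < dr) | (tie & (s.intensity[left] > s.intensity[right]))
    best = np.where(pick_left, left, right)
    best_d = np.where(pick_left, dl, dr)
    return np.where(best_d <= tol, best, -1)


class _LevelCache:
    """Per-spectrum feature/level cache shared by the collectors."""

    def __init__(self, model: SignificanceModel, half_width: float = LOCAL_WINDOW):
        self.model = model
        self.half_width = half_width
        self._feats: dict[str, np.ndarray] = {}

    def features(self, s: Spectrum) -> np.ndarray:
        if s.id not in self._feats:
            self._feats[s.id] = spectrum_features(s, half_width=self.half_width)
        return self._feats[s.id]

    def levels(self, s: Spectrum) -> np.ndarray:
        return np.log(self.features(s)) @ self.model.as_array()


def collect_signal_levels(
    pairs: Sequence[TrainingPair],
    spectra: Mapping[str, Spectrum],
    ion_type: IonType,
    tol: float = DEFAULT_FRAGMENT_TOL,
    model: SignificanceModel | None = None,
    cache: _LevelCache | None = None,
) -> list[LabeledLevel]:
    """Match every theoretical ion of ``ion_type`` over the training
    peptides to its nearest peak and record the peak's significance level
    (or a miss). Spectra should already have precursor peaks removed.
    """
    if cache is None:
        cache = _LevelCache(model if model is not None else SignificanceModel())
    out: list[LabeledLevel] = []
    for pair in pairs:
        if pair.spectrum_id not in spectra:
            raise KeyError(f"missing spectrum id {pair.spectrum_id!r}")
        s = spectra[pair.spectrum_id]
        ions = fragment_ions(pair.peptide, [ion_type])
        n = len(pair.peptide)
        feats = cache.features(s)
        levels = np.log(feats) @ cache.model.as_array()
        matches = _match_many(s, np.array([ion.mz for ion in ions]), tol)
        for ion, m in zip(ions, matches):
            cls = position_class(ion.site, n)
            if m < 0:
                out.append(LabeledLevel(None, "signal", ion_type.name, cls))
            else:
                out.append(
                    LabeledLevel(
                        float(levels[m]),
                        "signal",
                        ion_type.name,
                        cls,
                        PeakFeatures(*feats[m]),
                    )
                )
    return out


def collect_decoy_levels(
    spectra: Mapping[str, Spectrum],
    ion_counts: Mapping[str, int],
    count_multiplier: int = DEFAULT_DECOY_MULTIPLIER,
    tol: float = DEFAULT_FRAGMENT_TOL,
    model: SignificanceModel | None = None,
    seed: int = 42,
    cache: _LevelCache | None = None,
) -> list[LabeledLevel]:
    """Draw ``count_multiplier`` random m/z values per signal ion,
    uniformly over each spectrum's observed m/z range, and match them
    with the same rule as real ions.

    ``ion_counts`` maps spectrum id -> number of signal ions in that
    spectrum, so the decoy draws follow the spectra in proportion.
    """
    if count_multiplier < 1:
        raise ValueError("count_multiplier must be >= 1")
    if cache is None:
        cache = _LevelCache(model if model is not None else SignificanceModel())
    rng = np.random.default_rng(seed)
    out: list[LabeledLevel] = []
    for sid in sorted(ion_counts):
        s = spectra[sid]
        if len(s) == 0:
            logger.warning("decoy draw skipped for empty spectrum %s", sid)
            continue
        k = count_multiplier * ion_counts[sid]
        draws = rng.uniform(s.mz[0], s.mz[-1], size=k)
        feats = cache.features(s)
        levels = np.log(feats) @ cache.model.as_array()
        matches = _match_many(s, draws, tol)
        for m in matches:
            if m < 0:
                out.append(LabeledLevel(None, "decoy"))
            else:
                out.append(
                    LabeledLevel(float(levels[m]), "decoy", features=PeakFeatures(*feats[m]))
                )
    return out


def _level_array(records: Iterable[LabeledLevel | float]) -> np.ndarray:
    vals = []
    for r in records:
        if isinstance(r, LabeledLevel):
            if r.matched:
                vals.append(r.level)
        else:
            vals.append(float(r))
    return np.asarray(vals)


def roc_auc(signal_levels, decoy_levels) -> float:
    """AUC of the classifier "level <= threshold => signal".

    Mann-Whitney midrank formulation; lower levels indicate signal.
    MISS records are excluded. Accepts floats or LabeledLevels.
    """
    x = _level_array(signal_levels)
    y = _level_array(decoy_levels)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both classes must be nonempty")
    combined = np.concatenate([x, y])
    r = rankdata(combined)
    # U counts pairs with signal level > decoy level (+ half-ties)
    u = r[: len(x)].sum() - len(x) * (len(x) + 1) / 2
    return float(1.0 - u / (len(x) * len(y)))


def _auc_columns(levels: np.ndarray, n_signal: int) -> np.ndarray:
    """AUC for each column of a levels matrix whose first n_signal rows
    are signal."""
    r = rankdata(levels, axis=0)
    u = r[:n_signal].sum(axis=0) - n_signal * (n_signal + 1) / 2
    n_decoy = levels.shape[0] - n_signal
    return 1.0 - u / (n_signal * n_decoy)


def grid_search_coefficients(
    signal: Sequence[LabeledLevel],
    decoy: Sequence[LabeledLevel],
    grid_step: float = 0.01,
) -> SignificanceModel:
    """Exhaustive search for the feature coefficients.

    Fixes c_rl = 1 (local rank is the dominant feature) and enumerates
    c_rg, c_tg, c_tl over {grid_step, 2*grid_step, ..., 1}, maximizing
    the signal/decoy AUC; the winner is normalized to sum 1. Ties go to
    the lexicographically smallest (c_rg, c_tg, c_tl).
    """
    sig_f = np.array([r.features for r in signal if r.matched], dtype=float)
    dec_f = np.array([r.features for r in decoy if r.matched], dtype=float)
    if len(sig_f) == 0 or len(dec_f) == 0:
        raise ValueError("both classes need matched records with features")
    logf = np.log(np.vstack([sig_f, dec_f]))
    n_signal = len(sig_f)

    values = np.round(np.arange(grid_step, 1.0 + grid_step / 2, grid_step), 10)
    if len(values) == 0:
        raise ValueError("empty grid")
    combos = np.array(list(itertools.product(values, repeat=3)))  # lex order
    best_auc = -np.inf
    best: np.ndarray | None = None
    chunk = 2000
    for start in range(0, len(combos), chunk):
        block = combos[start : start + chunk]
        coef = np.column_stack(
            [block[:, 0], np.ones(len(block)), block[:, 1], block[:, 2]]
        )
        levels = logf @ coef.T
        aucs = _auc_columns(levels, n_signal)
        i = int(np.argmax(aucs))  # argmax returns the first = lex smallest
        if aucs[i] > best_auc:
            best_auc = float(aucs[i])
            best = block[i]
    c_rg, c_tg, c_tl = best
    total = c_rg + 1.0 + c_tg + c_tl
    model = SignificanceModel(c_rg / total, 1.0 / total, c_tg / total, c_tl / total)
    logger.info("grid search best AUC %.4f -> %s", best_auc, model)
    return model


@dataclass
class TrainingStats:
    """Bookkeeping from f-function training."""

    n: int  # total ions of the type/class
    m: int  # matched ions
    interval_counts: list[int]
    signal_probs: list[float]
    decoy_probs: list[float]
    decoy_total: int
    decoy_matched: int

    @property
    def match_frequency(self) -> float:
        return self.m / self.n


@dataclass
class IonScoreFunction:
    """Piecewise-linear approximation of the log likelihood-ratio f(x).

    ``knots`` are the interval centroids c1..c4 plus c5 (the centroid of
    the weakest 10% of matched levels); ``values`` the corresponding f.
    f is clamped to f(c1) below c1 and to f(c5) = miss_value above c5,
    and a non-matching ion also contributes miss_value.
    """

    knots: np.ndarray
    values: np.ndarray
    miss_value: float
    stats: TrainingStats | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.knots) != len(self.values):
            raise ValueError("knots and values must have equal length")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")

    def __call__(self, x: float | None) -> float:
        return evaluate_f(self, x)


def train_ion_score_function(
    levels: Sequence[LabeledLevel],
    min_matched: int = MIN_MATCHED_RECORDS,
    pseudocount: float = 0.5,
) -> IonScoreFunction:
    """Train f(x) for one ion type (and position class) from labeled
    significance levels.

    The matched signal levels are split into four intervals of (near)
    equal count; f at each interval centroid is the log ratio of the
    signal and decoy probabilities of falling in the interval, with
    probabilities normalized by all ions / all decoy draws so that each
    hypothesis' interval masses plus its miss mass sum to 1.
    """
    sig = [r for r in levels if r.label == "signal"]
    dec = [r for r in levels if r.label == "decoy"]
    matched = np.sort(_level_array(sig))
    n, m = len(sig), len(matched)
    if m < min_matched:
        raise ValueError(f"too few matched signal records: {m} < {min_matched}")
    if len(dec) == 0:
        raise ValueError("decoy records required")

    # interval sizes: ceil(m/4) for the first (m mod 4) intervals
    base, rem = divmod(m, 4)
    sizes = [base + 1] * rem + [base] * (4 - rem)
    edges = np.cumsum(sizes)
    groups = np.split(matched, edges[:-1])
    centroids = np.array([g.mean() for g in groups])
    # interval boundaries: midpoints between adjacent groups' extremes
    bounds = np.array(
        [(groups[j][-1] + groups[j + 1][0]) / 2 for j in range(3)]
    )

    dec_matched = _level_array(dec)
    D = len(dec)
    counts = np.histogram(dec_matched, bins=np.concatenate(([-np.inf], bounds, [np.inf])))[0]
    dec_counts = np.where(counts == 0, pseudocount, counts)
    sig_probs = np.array(sizes) / n
    dec_probs = dec_counts / D
    f_values = np.log(sig_probs / dec_probs)

    top = max(1, int(np.ceil(0.10 * m)))
    c5 = float(matched[-top:].mean())
    if c5 <= centroids[-1]:  # degenerate ties: keep knots strictly increasing
        c5 = centroids[-1] + 1e-9

    sig_miss = (n - m) if n > m else pseudocount
    dec_miss = (D - len(dec_matched)) if D > len(dec_matched) else pseudocount
    miss_value = float(np.log((sig_miss / n) / (dec_miss / D)))

    stats = TrainingStats(
        n=n,
        m=m,
        interval_counts=sizes,
        signal_probs=sig_probs.tolist(),
        decoy_probs=dec_probs.tolist(),
        decoy_total=D,
        decoy_matched=len(dec_matched),
    )
    return IonScoreFunction(
        knots=np.concatenate([centroids, [c5]]),
        values=np.concatenate([f_values, [miss_value]]),
        miss_value=miss_value,
        stats=stats,
    )


def evaluate_f(fn: IonScoreFunction, x: float | None) -> float:
    """Evaluate f at significance level ``x`` (None = no matching peak)."""
    if x is None:
        return fn.miss_value
    return float(np.interp(x, fn.knots, fn.values))
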