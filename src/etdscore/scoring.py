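"""Peptide-spectrum scoring: the log likelihood-ratio score

    log lambda = sum_{i,j} f_{i,j}(x_{i,j})

over the eight scored ETD ion types, where x_{i,j} is the significance
level of the peak matched by the j-th ion of type t_i (infinity / miss if
none) and f_{i,j} is the trained position-specific likelihood-ratio
function. Ions are treated as independent; peaks may be shared between
ion types.

Also houses the training pipeline that assembles a ScoringModel from
spectrum-peptide pairs, and structured-text (JSON) model serialization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .chem import (
    ION_TYPES,
    SCORED_ION_TYPE_NAMES,
    Peptide,
    fragment_ions,
    peptide_mass,
)
from .significance import SignificanceModel, spectrum_significance_levels
from .spectra import Spectrum
from .training import (
    DEFAULT_DECOY_MULTIPLIER,
    DEFAULT_FRAGMENT_TOL,
    MIN_MATCHED_RECORDS,
    POSITION_CLASSES,
    IonScoreFunction,
    LabeledLevel,
    TrainingPair,
    _LevelCache,
    _match_many,
    collect_decoy_levels,
    collect_signal_levels,
    evaluate_f,
    grid_search_coefficients,
    position_class,
    train_ion_score_function,
)

__all__ = [
    "MODEL_VERSION",
    "DEFAULT_PARENT_TOL_PPM",
    "ScoringModel",
    "IonRecord",
    "MatchResult",
    "score_peptide",
    "rank_candidates",
    "train_scoring_model",
    "save_model",
    "load_model",
]

logger = logging.getLogger("etdscore")

MODEL_VERSION = "1"
#: Parent-mass gate (ppm) applied when ranking candidates.
DEFAULT_PARENT_TOL_PPM = 10.0


@dataclass
class ScoringModel:
    """Bundle of trained components needed to score a peptide."""

    significance: SignificanceModel
    functions: Mapping[tuple[str, str], IonScoreFunction]
    ion_types: Sequence[str] = SCORED_ION_TYPE_NAMES
    fragment_tol: float = DEFAULT_FRAGMENT_TOL
    version: str = MODEL_VERSION

    def function_for(self, ion_type: str, cls: str) -> IonScoreFunction:
        try:
            return self.functions[(ion_type, cls)]
        except KeyError:
            raise KeyError(
                f"model has no score function for ion type {ion_type!r}, "
                f"position class {cls!r}"
            ) from None


class IonRecord(NamedTuple):
    ion_type: str
    site: int
    mz: float
    peak_index: int | None  # None = no matching peak
    level: float | None
    contribution: float


@dataclass
class MatchResult:
    peptide: Peptide
    records: list[IonRecord]
    score: float

    def contribution_by_type(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for r in self.records:
            out[r.ion_type] = out.get(r.ion_type, 0.0) + r.contribution
        return out


def score_peptide(
    s: Spectrum,
    p: Peptide,
    model: ScoringModel,
    _levels: np.ndarray | None = None,
) -> MatchResult:
    """Score one peptide against one (preprocessed) spectrum.

    Each theoretical ion of the scored types is matched to its nearest
    peak within the fragment tolerance (distance ties to the higher
    peak); the significance level of the matched peak is fed through the
    ion's f function, and the contributions are summed. ``_levels`` lets
    callers reuse precomputed per-peak significance levels.
    """
    if _levels is None:
        _levels = (
            spectrum_significance_levels(s, model.significance)
            if len(s)
            else np.empty(0)
        )
    n = len(p)
    records: list[IonRecord] = []
    for name in model.ion_types:
        ions = fragment_ions(p, [ION_TYPES[name]])
        matches = _match_many(s, np.array([ion.mz for ion in ions]), model.fragment_tol)
        for ion, m in zip(ions, matches):
            fn = model.function_for(name, position_class(ion.site, n))
            if m < 0:
                records.append(
                    IonRecord(name, ion.site, ion.mz, None, None, fn.miss_value)
                )
            else:
                level = float(_levels[m])
                records.append(
                    IonRecord(name, ion.site, ion.mz, int(m), level, evaluate_f(fn, level))
                )
    return MatchResult(p, records, sum(r.contribution for r in records))


def rank_candidates(
    s: Spectrum,
    candidates: Sequence[Peptide],
    model: ScoringModel,
    parent_tol_ppm: float = DEFAULT_PARENT_TOL_PPM,
) -> list[tuple[Peptide, float]]:
    """Score all candidates against ``s`` and order them best-first.

    Candidates whose mass disagrees with the precursor beyond
    ``parent_tol_ppm`` are reported via a warning but still scored, not
    silently dropped. Ties are broken by peptide string.
    """
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    M = s.precursor_neutral_mass
    bad = [
        p.sequence
        for p in candidates
        if abs(peptide_mass(p) - M) / M * 1e6 > parent_tol_ppm
    ]
    if bad:
        logger.warning(
            "spectrum %s: %d candidate(s) violate the %.1f ppm parent-mass "
            "tolerance: %s",
            s.id,
            len(bad),
            parent_tol_ppm,
            ", ".join(bad[:5]),
        )
    levels = (
        spectrum_significance_levels(s, model.significance) if len(s) else np.empty(0)
    )
    scored = [
        (p, score_peptide(s, p, model, _levels=levels).score) for p in candidates
    ]
    return sorted(scored, key=lambda t: (-t[1], t[0].sequence))


# ---------------------------------------------------------------------------
# Training pipeline


def train_scoring_model(
    pairs: Sequence[TrainingPair],
    spectra: Mapping[str, Spectrum],
    fragment_tol: float = DEFAULT_FRAGMENT_TOL,
    decoy_multiplier: int = DEFAULT_DECOY_MULTIPLIER,
    grid_step: float | None = None,
    seed: int = 42,
    coefficient_ion: str = "z'",
    parent_tol_ppm: float = DEFAULT_PARENT_TOL_PPM,
    min_matched: int = MIN_MATCHED_RECORDS,
) -> tuple[ScoringModel, pd.DataFrame]:
    """Train a full ScoringModel from spectrum-peptide pairs.

    Spectra must already be preprocessed (precursor peaks removed).
    When ``grid_step`` is given the significance coefficients are
    re-derived by grid search on the ``coefficient_ion`` signal vs decoy
    features; otherwise the published defaults are used. Position
    classes with fewer than ``min_matched`` matched ions fall back to the
    ion type's pooled (all-positions) function.

    Returns the model and a per-ion-type report (n, m, match frequency)
    covering all twelve ion types.
    """
    pairs = list(pairs)
    kept = []
    for pair in pairs:
        if pair.spectrum_id not in spectra:
            raise KeyError(f"missing spectrum id {pair.spectrum_id!r}")
        s = spectra[pair.spectrum_id]
        M = s.precursor_neutral_mass
        if abs(peptide_mass(pair.peptide) - M) / M * 1e6 > parent_tol_ppm:
            logger.warning(
                "dropping pair %s: peptide mass inconsistent with precursor",
                pair.spectrum_id,
            )
            continue
        kept.append(pair)
    if not kept:
        raise ValueError("no training pairs left after parent-mass check")

    # every ion type contributes one ion per fragmentation site
    ion_counts = {}
    for pair in kept:
        ion_counts[pair.spectrum_id] = (
            ion_counts.get(pair.spectrum_id, 0) + len(pair.peptide) - 1
        )

    # Stage 1: significance coefficients. Features do not depend on the
    # coefficients, so collection can run under the default model.
    cache = _LevelCache(SignificanceModel())
    if grid_step is not None:
        sig0 = collect_signal_levels(
            kept, spectra, ION_TYPES[coefficient_ion], fragment_tol, cache=cache
        )
        dec0 = collect_decoy_levels(
            spectra, ion_counts, decoy_multiplier, fragment_tol, seed=seed, cache=cache
        )
        significance = grid_search_coefficients(sig0, dec0, grid_step)
    else:
        significance = SignificanceModel()

    # Stage 2: per-(type, position class) f functions under the final
    # coefficients. One decoy pool is drawn and shared across types
    # (every type has the same ion count per spectrum).
    cache = _LevelCache(significance)
    decoys = collect_decoy_levels(
        spectra, ion_counts, decoy_multiplier, fragment_tol, seed=seed, cache=cache
    )
    decoy_match_rate = sum(1 for r in decoys if r.matched) / len(decoys)
    functions: dict[tuple[str, str], IonScoreFunction] = {}
    report_rows = []
    for name in ION_TYPES:
        signal = collect_signal_levels(
            kept, spectra, ION_TYPES[name], fragment_tol, cache=cache
        )
        n = len(signal)
        m = sum(1 for r in signal if r.matched)
        freq = m / n if n else np.nan
        # Raw match frequency is inflated by accidental matches against
        # noise; the decoy match rate gives a calibrated correction.
        corrected = (freq - decoy_match_rate) / (1.0 - decoy_match_rate)
        report_rows.append(
            {
                "ion_type": name,
                "n": n,
                "m": m,
                "frequency": freq,
                "corrected_frequency": float(np.clip(corrected, 0.0, 1.0)),
            }
        )
        if name not in SCORED_ION_TYPE_NAMES:
            continue
        pooled = train_ion_score_function(signal + decoys, min_matched=min_matched)
        for cls in POSITION_CLASSES:
            class_signal = [r for r in signal if r.position_class == cls]
            n_matched = sum(1 for r in class_signal if r.matched)
            if n_matched >= min_matched:
                functions[(name, cls)] = train_ion_score_function(
                    class_signal + decoys, min_matched=min_matched
                )
            else:
                logger.info(
                    "ion type %s class %s: %d matched < %d, pooled fallback",
                    name,
                    cls,
                    n_matched,
                    min_matched,
                )
                functions[(name, cls)] = pooled

    model = ScoringModel(
        significance=significance,
        functions=functions,
        ion_types=SCORED_ION_TYPE_NAMES,
        fragment_tol=fragment_tol,
    )
    report = pd.DataFrame(report_rows).sort_values(
        "frequency", ascending=False, ignore_index=True
    )
    return model, report


# ---------------------------------------------------------------------------
# Serialization (structured text, round-trip stable)


def save_model(model: ScoringModel, path) -> None:
    doc = {
        "version": model.version,
        "fragment_tol": model.fragment_tol,
        "ion_types": list(model.ion_types),
        "significance": {
            "c_rg": model.significance.c_rg,
            "c_rl": model.significance.c_rl,
            "c_tg": model.significance.c_tg,
            "c_tl": model.significance.c_tl,
        },
        "functions": {
            f"{name}|{cls}": {
                "knots": fn.knots.tolist(),
                "values": fn.values.tolist(),
                "miss_value": fn.miss_value,
            }
            for (name, cls), fn in model.functions.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path) -> ScoringModel:
    with open(path) as fh:
        doc = json.load(fh)
    functions = {}
    for key, spec in doc["functions"].items():
        name, cls = key.rsplit("|", 1)
        functions[(name, cls)] = IonScoreFunction(
            knots=np.array(spec["knots"]),
            values=np.array(spec["values"]),
            miss_value=spec["miss_value"],
        )
    return ScoringModel(
        significance=SignificanceModel(**doc["significance"]),
        functions=functions,
        ion_types=tuple(doc["ion_types"]),
        fragment_tol=doc["fragment_tol"],
        version=doc["version"],
    )
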