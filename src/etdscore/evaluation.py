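"""De novo sequencing evaluation: residue-level accuracies and longest
correct consecutive subsequence (L_max) statistics.

A predicted residue is counted correct when the true peptide contains a
residue of the same code (I and L merged — their masses are identical)
whose two flanking prefix masses both agree with the predicted residue's
within the tolerance (default 0.6 Da). This is mass-position matching,
the field's standard, not string alignment.

Accuracy I divides total correct residues by total TRUE peptide length;
Accuracy II (the measure used by earlier de novo work) divides by total
PREDICTED length, which unfairly favours methods that output fewer
residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import Peptide

__all__ = [
    "DEFAULT_EVAL_TOL",
    "PredictionRecord",
    "EvaluationReport",
    "correct_residues",
    "accuracies",
    "lmax",
    "evaluate_predictions",
]

#: Position tolerance (Da) for a predicted residue to count as correct.
DEFAULT_EVAL_TOL = 0.6

_LMAX_RANGE = range(3, 11)


@dataclass(frozen=True)
class PredictionRecord:
    spectrum_id: str
    true_peptide: Peptide
    predicted_peptide: Peptide


@dataclass(frozen=True)
class EvaluationReport:
    accuracy_I: float
    accuracy_II: float
    average_length: float
    lmax_counts: dict[int, float]  # l -> fraction of predictions with L_max >= l


def _prefixes(p: Peptide) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(p.residue_masses())])


def _code(c: str) -> str:
    return "L" if c == "I" else c


def _match_matrix(true_p: Peptide, pred_p: Peptide, tol: float) -> np.ndarray:
    """M[i, j]: predicted residue i+1 is a correct rendering of true
    residue j+1 (same code with I/L merged, both flanking prefix masses
    within tol)."""
    tp = _prefixes(true_p)
    pp = _prefixes(pred_p)
    codes_ok = np.array(
        [
            [_code(a) == _code(b) for b in true_p.sequence]
            for a in pred_p.sequence
        ]
    )
    left_ok = np.abs(pp[:-1, None] - tp[None, :-1]) <= tol
    right_ok = np.abs(pp[1:, None] - tp[None, 1:]) <= tol
    return codes_ok & left_ok & right_ok


def correct_residues(true_p: Peptide, pred_p: Peptide, tol: float = DEFAULT_EVAL_TOL) -> int:
    """Number of predicted residues that are correct."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    return int(_match_matrix(true_p, pred_p, tol).any(axis=1).sum())


def lmax(true_p: Peptide, pred_p: Peptide, tol: float = DEFAULT_EVAL_TOL) -> int:
    """Length of the longest run of consecutive correct predicted
    residues anchored to consecutive true residues."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    M = _match_matrix(true_p, pred_p, tol)
    npred, ntrue = M.shape
    best = 0
    for offset in range(-(npred - 1), ntrue):
        run = 0
        for i in range(npred):
            j = i + offset
            if 0 <= j < ntrue and M[i, j]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def accuracies(
    records: Sequence[PredictionRecord], tol: float = DEFAULT_EVAL_TOL
) -> tuple[float, float, float]:
    """(accuracy_I, accuracy_II, average predicted length)."""
    if not records:
        raise ValueError("record list must be nonempty")
    correct = sum(
        correct_residues(r.true_peptide, r.predicted_peptide, tol) for r in records
    )
    true_total = sum(len(r.true_peptide) for r in records)
    pred_total = sum(len(r.predicted_peptide) for r in records)
    return (
        correct / true_total,
        correct / pred_total,
        pred_total / len(records),
    )


def evaluate_predictions(
    records: Sequence[PredictionRecord], tol: float = DEFAULT_EVAL_TOL
) -> EvaluationReport:
    """Full report: both accuracies, average length, and the fraction of
    predictions whose L_max reaches each l in 3..10."""
    acc1, acc2, avg_len = accuracies(records, tol)
    lmaxes = [lmax(r.true_peptide, r.predicted_peptide, tol) for r in records]
    counts = {
        l: sum(1 for v in lmaxes if v >= l) / len(lmaxes) for l in _LMAX_RANGE
    }
    return EvaluationReport(acc1, acc2, avg_len, counts)
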