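"""Evaluation battery for 4-class HER2 scoring.

Covers the metrics used to characterize the scorer: the 4x4 confusion
matrix and overall accuracy; per-class specificity TN_i / (TN_i + FP_i);
accuracy restricted to adjacent score pairs (0 vs 1+, 1+ vs 2+, 2+ vs 3+),
which carry the clinical decision boundaries; and ROC/AUC for the three
binary groupings 0 vs rest, {0,1+} vs {2+,3+}, and {0,1+,2+} vs 3+,
computed from per-core probabilities obtained by averaging the k most
confident replicate predictions.

ROC curves are built by an explicit threshold sweep over unique scores
with trapezoidal AUC; tests cross-check the AUC against a rank-based
Mann-Whitney U oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import PredictionRecord, kcs_select
from .labels import ScoreLabel, parse_score

__all__ = [
    "confusion_matrix",
    "overall_accuracy",
    "per_class_specificity",
    "adjacent_pair_accuracy",
    "averaged_confident_probs",
    "grouped_roc_auc",
    "RocCurve",
    "GROUPINGS",
]

N_CLASSES = 4

#: Binary HER2 groupings: name -> set of positive classes.
GROUPINGS = {
    "0_vs_rest": frozenset({1, 2, 3}),
    "01_vs_23": frozenset({2, 3}),
    "012_vs_3": frozenset({3}),
}


def _as_int_labels(labels) -> np.ndarray:
    return np.array([int(parse_score(l)) for l in labels], dtype=np.int64)


def confusion_matrix(true, pred) -> np.ndarray:
    """4x4 count matrix, rows = true class, columns = predicted class."""
    t = _as_int_labels(true)
    p = _as_int_labels(pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def overall_accuracy(cm: np.ndarray) -> float:
    """Trace over total of a confusion matrix."""
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def per_class_specificity(cm: np.ndarray) -> np.ndarray:
    """Specificity_i = TN_i / (TN_i + FP_i) from confusion-matrix marginals.

    TN_i counts cores correctly identified as not class i, FP_i cores
    incorrectly called class i. A class with a degenerate denominator
    (every core truly belongs to it) yields NaN with a warning rather than
    a silent zero.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    out = np.empty(N_CLASSES)
    for i in range(N_CLASSES):
        fp = cm[:, i].sum() - cm[i, i]
        tn = total - cm[i, :].sum() - cm[:, i].sum() + cm[i, i]
        denom = tn + fp
        if denom == 0:
            warnings.warn(
                f"specificity undefined for class {i}: no true negatives exist",
                RuntimeWarning,
            )
            out[i] = np.nan
        else:
            out[i] = tn / denom
    return out


def adjacent_pair_accuracy(true, pred, pair: tuple[int, int]) -> float:
    """Accuracy on the subset whose true label lies in an adjacent pair.

    Restricted to cores with true label in ``pair = (a, a+1)``; a core is
    counted correct only when the prediction equals its true label — a
    prediction outside the pair is an error. Returns NaN with a warning if
    the subset is empty.
    """
    a, b = (int(parse_score(p)) for p in pair)
    if b != a + 1:
        raise ValueError(f"pair must be ordinally adjacent, got ({a}, {b})")
    t = _as_int_labels(true)
    p = _as_int_labels(pred)
    mask = (t == a) | (t == b)
    if not mask.any():
        warnings.warn(
            f"no cores with true label in pair ({a}, {b}); accuracy undefined",
            RuntimeWarning,
        )
        return float("nan")
    return float((t[mask] == p[mask]).mean())


def averaged_confident_probs(records: list[PredictionRecord], k: int) -> np.ndarray:
    """Mean probability vector of the k most confident replicate records.

    Reuses the KCS selection (margin ranking, seed tie-break); the mean of
    points on the probability simplex is on the simplex already, so the
    final renormalization is a numerical no-op.
    """
    if not records:
        raise ValueError("no prediction records supplied")
    kcs = kcs_select(records, k)
    mean = np.mean([r.probs for r in kcs], axis=0)
    return mean / mean.sum()


@dataclass
class RocCurve:
    """ROC points (FPR, TPR ordered from (0,0) to (1,1)) and trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    grouping: str = ""


def grouped_roc_auc(true, probs, grouping: str) -> RocCurve:
    """ROC/AUC for one binary HER2 grouping from class probabilities.

    The positive-group score of a core is the summed probability over the
    grouping's positive classes; the curve sweeps thresholds over the
    unique scores. Raises if either group is empty (AUC undefined).
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; one of {sorted(GROUPINGS)}")
    positive = GROUPINGS[grouping]
    t = _as_int_labels(true)
    p = np.asarray(probs, dtype=np.float64)
    if p.shape != (len(t), N_CLASSES):
        raise ValueError(f"probs must be (n, 4), got {p.shape}")
    y = np.isin(t, list(positive))
    if y.all() or not y.any():
        raise ValueError(
            f"grouping {grouping!r} has a single class present; AUC undefined"
        )
    score = p[:, sorted(positive)].sum(axis=1)

    order = np.argsort(-score, kind="stable")
    y_sorted = y[order]
    s_sorted = score[order]
    # cumulative counts at each unique-threshold boundary
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc, grouping=grouping)
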