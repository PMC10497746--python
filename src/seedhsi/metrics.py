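"""Detection metrics (precision, recall, F1, AP, mAP) and regression
metrics (R-squared, RMSE) with exact textbook semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "precision_recall_f1",
    "average_precision",
    "mean_average_precision",
    "r_squared",
    "rmse",
]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be nonnegative")


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float, bool]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

    Undefined denominators yield 0 by convention; the trailing boolean flags
    that any convention was applied.
    """
    flagged = False
    if counts.TP + counts.FP > 0:
        p = counts.TP / (counts.TP + counts.FP)
    else:
        p, flagged = 0.0, True
    if counts.TP + counts.FN > 0:
        r = counts.TP / (counts.TP + counts.FN)
    else:
        r, flagged = 0.0, True
    if p + r > 0:
        f1 = 2 * p * r / (p + r)
    else:
        f1, flagged = 0.0, True
    return p, r, f1, flagged


def average_precision(scores, truth, n_positives: int | None = None) -> float:
    """Area under the precision-recall curve by descending-threshold steps.

    ``scores`` are detection confidences, ``truth`` boolean flags.  At every
    distinct threshold the (recall, precision) point is computed and the area
    accumulated as sum of (delta recall) x precision — the exact step-curve
    area over all points.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have matching shapes")
    n_pos = int(truth.sum()) if n_positives is None else int(n_positives)
    if n_pos < 1:
        raise ValueError("average precision needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, t = scores[order], truth[order]
    ap = 0.0
    prev_recall = 0.0
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # process one distinct threshold at a time
            tp += int(t[j])
            fp += int(not t[j])
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def mean_average_precision(per_class_ap) -> float:
    """Arithmetic mean of per-class average precisions."""
    ap = np.asarray(per_class_ap, dtype=float)
    if ap.size == 0:
        raise ValueError("empty AP vector")
    return float(ap.mean())


def r_squared(actual, predicted) -> float:
    """Coefficient of determination: 1 - SSR/SST."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("actual and predicted must be equal-length vectors, n >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R-squared undefined for constant actual values")
    ssr = float(np.sum((y - yhat) ** 2))
    return 1.0 - ssr / sst


def rmse(actual, predicted) -> float:
    """Root-mean-square error of predictions."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("actual and predicted must be equal-length vectors, n >= 1")
    return math.sqrt(float(np.mean((y - yhat) ** 2)))
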