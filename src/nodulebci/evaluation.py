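"""Detection metrics for scored epoch sets: SEN / SPE / FPF and ROC / AUC.

SEN = TP/(TP+FN) and SPE = TN/(TN+FP) are the usual sensitivity and
specificity.  FPF here is the *combined-numerator* false positive fraction
(FP+FN)/(TP+FP+TN+FN) — a misclassification-style rate rather than the
conventional false positive rate, kept in that form for fidelity to the
protocol's definition; the conventional FPR = FP/(FP+TN) is exported
alongside under its own name.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DataError, ValidationError

__all__ = ["ConfusionCounts", "ROCCurve", "confusion", "metrics", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("counts must be non-negative")
        if self.total < 1:
            raise ValidationError("confusion table must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ROCCurve:
    """Threshold sweep with trapezoidal AUC; ties share a threshold step."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Counts of a binary prediction against binary labels."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.size == 0:
        raise ValidationError("empty input")
    if labels.shape != predictions.shape:
        raise ValidationError("labels and predictions must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("labels must be binary")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """SEN, SPE, the combined-numerator FPF, and conventional FPR.

    A metric with a zero denominator is returned as NaN (flagged undefined)
    rather than silently zero.
    """
    sen = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    spe = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    fpf = (c.fp + c.fn) / c.total
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) > 0 else float("nan")
    return {"sen": sen, "spe": spe, "fpf": fpf, "fpr_conventional": fpr}


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC over the unique-score threshold sweep, AUC by trapezoid.

    Tie-free inputs satisfy the rank-statistic identity
    AUC = U / (n_pos * n_neg) with U the Mann-Whitney statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise DataError("both classes must be present for a ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)
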