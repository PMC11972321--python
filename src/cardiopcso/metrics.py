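"""Confusion-matrix metrics, ROC/AUC, and overlap scores.

Accuracy, precision, recall and F1 follow the usual confusion-matrix
definitions.  The F1 default is the harmonic mean 2PR/(P+R); a halved
variant (``variant="printed"``) is available for comparison with sources
that print F1 = (1/2)·PR/(P+R).  Degenerate denominators return 0 with a
logged warning so batch evaluation never fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "f1_score",
    "tpr",
    "fpr",
    "roc_curve",
    "auc",
    "iou",
    "report_from_predictions",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exhaustive TP/TN/FP/FN tally over binary vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    for v in (y_true, y_pred):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        log.warning("%s has zero denominator; defined as 0", name)
        return 0.0
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.n, "accuracy")


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "recall")


def f1_score(c: ConfusionCounts, variant: str = "harmonic") -> float:
    """F1 = 2PR/(P+R) by default; ``variant="printed"`` gives (1/2)PR/(P+R)."""
    p, r = precision(c), recall(c)
    base = _ratio(p * r, p + r, "f1")
    if variant == "harmonic":
        return 2.0 * base
    if variant == "printed":
        return 0.5 * base
    raise ValueError(f"unknown F1 variant {variant!r}")


def tpr(c: ConfusionCounts) -> float:
    return recall(c)


def fpr(c: ConfusionCounts) -> float:
    return _ratio(c.fp, c.tn + c.fp, "fpr")


def roc_curve(y_true, scores) -> tuple[np.ndarray, np.ndarray]:
    """Threshold sweep over the unique scores (ties grouped), anchored at
    (0,0) and (1,1).  Returns (fpr, tpr) arrays in increasing-fpr order."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    ys = y_true[order]
    ss = scores[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    # keep only the last index of each tied-score group
    last = np.r_[np.flatnonzero(np.diff(ss)), ss.size - 1]
    fpr_arr = np.r_[0.0, fps[last] / n_neg]
    tpr_arr = np.r_[0.0, tps[last] / n_pos]
    return fpr_arr, tpr_arr


def auc(fpr_arr, tpr_arr) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(tpr_arr, fpr_arr))


def iou(pred_mask, true_mask, class_id: int = 1) -> float:
    """Intersection over union for one class; 1.0 when both masks are empty."""
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError("shape mismatch")
    a = pred_mask == class_id
    b = true_mask == class_id
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


@dataclass
class MetricReport:
    """Bundle of classification metrics, optionally with a fold breakdown."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    tpr: float
    fpr: float
    auc: float | None = None
    dice: dict | None = None
    iou: dict | None = None
    folds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "auc": self.auc,
        }
        if self.dice is not None:
            d["dice"] = self.dice
        if self.iou is not None:
            d["iou"] = self.iou
        if self.folds:
            d["folds"] = self.folds
        return d


def report_from_predictions(y_true, y_pred, scores=None) -> MetricReport:
    c = confusion(y_true, y_pred)
    a = None
    if scores is not None:
        fp_, tp_ = roc_curve(y_true, scores)
        a = auc(fp_, tp_)
    return MetricReport(
        accuracy=accuracy(c),
        precision=precision(c),
        recall=recall(c),
        f1=f1_score(c),
        tpr=tpr(c),
        fpr=fpr(c),
        auc=a,
    )
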