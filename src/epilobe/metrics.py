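"""Classification metrics from confusion counts.

Implements specificity, accuracy, precision, recall, F1, and the
Matthews correlation coefficient directly from TP/TN/FP/FN counts.
Multi-class (lobe) evaluation uses one-vs-rest counts per class with a
macro average; a zero factor in the MCC denominator yields MCC = 0 by
convention (logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ConfusionCounts", "MetricsReport", "compute_metrics", "confusion_from_labels", "multiclass_report"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    specificity: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    counts: ConfusionCounts = None

    def as_dict(self, percent=False):
        s = 100.0 if percent else 1.0
        return {
            "SP": self.specificity * s,
            "AC": self.accuracy * s,
            "PR": self.precision * s,
            "RE": self.recall * s,
            "F1": self.f1 * s,
            "MCC": self.mcc * s,
        }


def _safe_div(num, den):
    return num / den if den > 0 else 0.0


def compute_metrics(counts):
    """All six metrics from one confusion quadruple."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated segments")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sp = _safe_div(tn, tn + fp)
    ac = (tp + tn) / counts.total
    pr = _safe_div(tp, tp + fp)
    re = _safe_div(tp, tp + fn)
    f1 = _safe_div(2.0 * pr * re, pr + re)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.info("degenerate MCC denominator; reporting MCC = 0 by convention")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(sp, ac, pr, re, f1, mcc, counts=counts)


def confusion_from_labels(y_true, y_pred, positive=1):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    tn = int(np.sum((y_pred != positive) & (y_true != positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))
    return ConfusionCounts(tp, tn, fp, fn)


def multiclass_report(y_true, y_pred, classes):
    """One-vs-rest report per class plus a macro average and micro accuracy."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    per_class = {}
    for c in classes:
        per_class[c] = compute_metrics(confusion_from_labels(y_true == c, y_pred == c, True))
    macro = {
        k: float(np.mean([r.as_dict()[k] for r in per_class.values()]))
        for k in ("SP", "AC", "PR", "RE", "F1", "MCC")
    }
    micro_accuracy = float(np.mean(y_true == y_pred)) if len(y_true) else 0.0
    return {"per_class": per_class, "macro": macro, "accuracy": micro_accuracy}
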