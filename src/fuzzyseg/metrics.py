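"""Confusion-matrix metrics and ROC/AUC for binary classification.

Positive class is +1 (malignant).  Metrics with a 0/0 denominator are
reported as NaN; MCC with any zero factor under the root is reported as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "binary_metrics",
    "roc_auc",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Standard 2x2 tally with +1 as the positive class."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    if set(np.unique(t)) - {-1, 1} or set(np.unique(p)) - {-1, 1}:
        raise ValueError("labels must be in {-1, +1}")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == -1) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == -1)).sum()),
        tn=int(((t == -1) & (p == -1)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def binary_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, PPV, NPV and MCC."""
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    prod = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(prod) if prod > 0 else 0.0
    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "accuracy": _ratio(tp + tn, c.total),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "mcc": mcc,
    }


def roc_auc(scores, y_true):
    """ROC curve (FPR, TPR at each distinct threshold) and trapezoidal AUC.

    Equal scores are grouped, which makes the trapezoidal area equal to the
    concordance probability with ties counted one half.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y_true)
    n_pos = int((t == 1).sum())
    n_neg = int((t == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    tps = np.cumsum(t_sorted == 1)
    fps = np.cumsum(t_sorted == -1)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, s.size - 1]
    tpr = np.r_[0.0, tps[idx] / n_pos]
    fpr = np.r_[0.0, fps[idx] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def metrics_report(metrics: dict[str, float], path=None) -> str:
    """Serialize a metric record as JSON (NaN rendered as null)."""
    clean = {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in metrics.items()}
    text = json.dumps(clean, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
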