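"""Confusion-matrix construction and classification performance metrics.

Positive = reflux-patient limb (label 1).  Metrics are reported in percent:

    sensitivity (TPR) = TP / (TP + FN)
    precision   (PPV) = TP / (TP + FP)
    accuracy    (ACC) = (TP + TN) / (TP + TN + FP + FN)
    F-measure         = 2 * precision * recall / (precision + recall)

A metric whose denominator is zero is reported as ``None`` (undefined),
never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def as_dict(self) -> dict:
        return {"tp": int(self.tp), "fn": int(self.fn),
                "tn": int(self.tn), "fp": int(self.fp)}


@dataclass(frozen=True)
class MetricsReport:
    """The four performance metrics in percent; ``None`` marks undefined."""

    sensitivity: Optional[float]
    precision: Optional[float]
    accuracy: Optional[float]
    f_measure: Optional[float]

    def as_dict(self) -> dict:
        return {"sensitivity": self.sensitivity, "precision": self.precision,
                "accuracy": self.accuracy, "f_measure": self.f_measure}


def confusion(labels, predictions) -> ConfusionMatrix:
    """Count TP/FN/TN/FP with positive = label 1."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and predictions must be 1D of equal length")
    for arr, name in ((y, "labels"), (p, "predictions")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    y = y.astype(int)
    p = p.astype(int)
    return ConfusionMatrix(tp=int(np.sum((y == 1) & (p == 1))),
                           fn=int(np.sum((y == 1) & (p == 0))),
                           tn=int(np.sum((y == 0) & (p == 0))),
                           fp=int(np.sum((y == 0) & (p == 1))))


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute the four metrics (percent) from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    prec = 100.0 * cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    if sens is None or prec is None or sens + prec == 0:
        f: Optional[float] = None
    else:
        f = 2.0 * sens * prec / (sens + prec)
    return MetricsReport(sensitivity=sens, precision=prec, accuracy=acc,
                         f_measure=f)
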