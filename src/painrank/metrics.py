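"""Imbalance-robust classification metrics from confusion counts.

With ~1 pain (P) gene per 40 non-pain (NP) genes, plain accuracy is
uninformative: a constant-NP predictor scores ~97.6%. The four metrics
here — Matthews correlation coefficient (MCC), geometric mean of
sensitivity and specificity (GM), F1 and balanced accuracy (BA) — all
reward performance on *both* classes and are the quantities the ensemble
is selected and benchmarked on.

Zero-denominator conventions (degenerate folds are routine at 1:40
imbalance): MCC is 0 when any marginal factor is 0; a sensitivity or
specificity with an empty class is 0; F1 is 0 when precision + recall = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_from_predictions",
    "mcc",
    "gm",
    "f1",
    "balanced_accuracy",
    "metric_set",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table for the binary pain / non-pain task.

    Class 1 is the pain (P) class throughout.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        """Recall on the pain class; 0 if there are no true positives at all."""
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    recall = sensitivity


@dataclass(frozen=True)
class MetricSet:
    """The four selection metrics, bundled per fold / per model."""

    mcc: float
    gm: float
    f1: float
    ba: float

    def as_dict(self) -> dict[str, float]:
        return {"mcc": self.mcc, "gm": self.gm, "f1": self.f1, "ba": self.ba}


def confusion_from_predictions(truth, predicted) -> ConfusionCounts:
    """Tally a confusion table from hard 0/1 labels (1 = pain)."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise ValueError(
            f"truth and predicted must be equal-length 1-D vectors, got shapes {t.shape} and {p.shape}"
        )
    for name, v in (("truth", t), ("predicted", p)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} contains non-binary labels; expected values in {{0, 1}}")
    t = t.astype(bool)
    p = p.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def gm(c: ConfusionCounts) -> float:
    """Geometric mean of sensitivity and specificity."""
    return math.sqrt(c.sensitivity * c.specificity)


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    s = c.precision + c.recall
    if s == 0:
        return 0.0
    return 2.0 * c.precision * c.recall / s


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    return 0.5 * (c.sensitivity + c.specificity)


def metric_set(c: ConfusionCounts) -> MetricSet:
    return MetricSet(mcc=mcc(c), gm=gm(c), f1=f1(c), ba=balanced_accuracy(c))
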