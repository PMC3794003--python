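"""Binary classification metrics: Sn, Sp, Ac, the Matthews correlation and ROC/AUC.

Conventions: alkaline is the positive class.  TP counts correctly
recognised alkaline samples, TN correctly recognised acidic samples, FN
alkaline predicted acidic, FP acidic predicted alkaline.

    Sn = TP / (TP + FN)            sensitivity (alkaline recall)
    Sp = TN / (TN + FP)            specificity (acidic recall)
    Ac = (TP + TN) / total         overall accuracy
    CC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

CC is the Matthews correlation coefficient; by convention it is 0 when any
factor of the denominator vanishes.  AUC is the area under the ROC curve,
equivalently the probability that a random positive scores above a random
negative with ties counted one half.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .sequence_io import ACIDIC, ALKALINE


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP/TN with alkaline as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_alkaline(self) -> int:
        return self.tp + self.fn

    @property
    def n_acidic(self) -> int:
        return self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn, self.fp + other.fp, self.tn + other.tn
        )


@dataclass
class PerformanceReport:
    """Sn, Sp, Ac, CC (and optionally AUC) derived from confusion counts."""

    sensitivity: float
    specificity: float
    accuracy: float
    correlation_coefficient: float
    auc: float | None = None
    counts: ConfusionCounts | None = None

    def to_dict(self) -> dict:
        out = {
            "sn": self.sensitivity,
            "sp": self.specificity,
            "ac": self.accuracy,
            "cc": self.correlation_coefficient,
            "auc": self.auc,
        }
        if self.counts is not None:
            out.update(asdict(self.counts))
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def __str__(self) -> str:
        lines = [
            f"Sn = {percent(self.sensitivity)}%",
            f"Sp = {percent(self.specificity)}%",
            f"Ac = {percent(self.accuracy)}%",
            f"CC = {self.correlation_coefficient:.4f}",
        ]
        if self.auc is not None:
            lines.append(f"AUC = {self.auc:.3f}")
        return "\n".join(lines)


def percent(fraction: float, decimals: int = 1) -> float:
    """Format a fraction as a percentage rounded half-up to one decimal."""
    q = Decimal(10) ** -decimals
    return float(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))


def compute_metrics(counts: ConfusionCounts) -> PerformanceReport:
    """Sn, Sp, Ac and Matthews CC from confusion counts.

    Raises
    ------
    ValueError
        On an empty confusion table or when a class is absent (the
        corresponding rate is undefined).
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    if counts.n_alkaline == 0:
        raise ValueError("no alkaline samples: sensitivity undefined")
    if counts.n_acidic == 0:
        raise ValueError("no acidic samples: specificity undefined")
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    cc = 0.0 if denom2 == 0 else (tp * tn - fp * fn) / math.sqrt(denom2)
    return PerformanceReport(
        sensitivity=tp / counts.n_alkaline,
        specificity=tn / counts.n_acidic,
        accuracy=counts.accuracy,
        correlation_coefficient=cc,
        counts=counts,
    )


def roc_auc(
    scores: Sequence[float] | np.ndarray,
    labels: Sequence[str] | np.ndarray,
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and AUC for alkaline-class scores.

    The curve sweeps a threshold over the distinct scores (ties grouped);
    the AUC is its trapezoidal area, identical to the pairwise-concordance
    probability with ties counted 0.5.

    Returns ``(points, auc)`` where points are (FPR, TPR) pairs.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    y = labels == ALKALINE
    if y.all() or (~y).all():
        missing = ACIDIC if y.all() else ALKALINE
        raise ValueError(f"cannot build a ROC curve: no {missing} samples")
    fpr, tpr, _ = roc_curve(y.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc
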