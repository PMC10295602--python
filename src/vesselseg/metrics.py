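"""Pixel-level segmentation statistics.

Segmentation is scored as per-pixel binary classification: each pixel is
either vessel (positive) or background. From the confusion counts
TP/FP/FN/TN the five standard statistics follow:

    accuracy  = (TP + TN) / (TP + FP + FN + TN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    IoU       = TP / (TP + FP + FN)

F1 here is the Dice coefficient (the F-measure at beta = 1), and on
shared counts it relates to IoU by the exact identity
F1 = 2*IoU / (1 + IoU). Counting is integer-exact; division happens only
at the end. When a field-of-view ROI mask is supplied, only pixels
inside it are tallied (pixels outside a fundus photograph's circular
aperture carry no information); this restriction is the default
whenever an ROI exists but can be turned off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts", "compute_metrics", "aggregate"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    iou: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        return {
            k: scale * getattr(self, k)
            for k in ("accuracy", "precision", "recall", "f1", "iou")
        }


def _check_binary(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0, 1}})")
    return arr.astype(bool)


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray, roi: Optional[np.ndarray] = None
) -> ConfusionCounts:
    """Tally TP/FP/FN/TN over all pixels, or over ROI pixels when given."""
    pred = _check_binary("pred", pred)
    truth = _check_binary("truth", truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if roi is not None:
        roi = _check_binary("roi", roi)
        if roi.shape != truth.shape:
            raise ValueError(f"roi shape {roi.shape} does not match {truth.shape}")
        pred, truth = pred[roi], truth[roi]
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """The five statistics from one set of counts.

    Zero-denominator cases (e.g. precision with no predicted positives)
    return 0 and are named in ``undefined`` rather than raising, so that
    batch evaluation stays total.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    undefined: set[str] = set()
    accuracy = (c.tp + c.tn) / c.total
    precision = _ratio(c.tp, c.tp + c.fp, "precision", undefined)
    recall = _ratio(c.tp, c.tp + c.fn, "recall", undefined)
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        undefined.add("f1")
        f1 = 0.0
    iou = _ratio(c.tp, c.tp + c.fp + c.fn, "iou", undefined)
    return MetricsReport(accuracy, precision, recall, f1, iou, frozenset(undefined))


def aggregate(
    items: Sequence[ConfusionCounts | MetricsReport], mode: str = "micro"
) -> MetricsReport:
    """Pool a collection of per-image results.

    ``micro`` sums confusion counts and computes the statistics once
    (every pixel weighted equally); ``macro`` averages per-image
    statistics (every image weighted equally). micro requires counts.
    """
    if not items:
        raise ValueError("cannot aggregate an empty collection")
    if mode == "micro":
        if not all(isinstance(i, ConfusionCounts) for i in items):
            raise TypeError("micro aggregation needs ConfusionCounts")
        total = items[0]
        for c in items[1:]:
            total = total + c
        return compute_metrics(total)
    if mode == "macro":
        reports = [compute_metrics(i) if isinstance(i, ConfusionCounts) else i for i in items]
        undefined = frozenset().union(*(r.undefined for r in reports))
        mean = lambda k: float(np.mean([getattr(r, k) for r in reports]))
        return MetricsReport(
            mean("accuracy"), mean("precision"), mean("recall"), mean("f1"), mean("iou"), undefined
        )
    raise ValueError(f"unknown aggregation mode {mode!r}; expected micro or macro")
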