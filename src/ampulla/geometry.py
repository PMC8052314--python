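"""Bounding-box geometry and detection evaluation metrics.

A bounding box is stored as the upper-left corner plus width and height, in
pixel units, matching the annotation convention of single-object endoscopic
datasets (one ampulla of Vater per image).  Coordinates are 0-based and a box
covers the half-open range ``[x, x + w) x [y, y + h)``, so its area is simply
``w * h``.  Coordinates may be real-valued; rasterization, where needed,
rounds to the nearest pixel.

The metrics here are the ones used to score single-object detectors:

* intersection-over-union (IoU) of two boxes,
* area precision / recall (overlap area divided by the predicted / ground
  truth box area),
* the relative centroid distance
  ``1/2 (|x_g - x_e| / W + |y_g - y_e| / H)`` between the ground-truth and
  estimated box centroids, normalized by the image width ``W`` and height
  ``H``,
* success curves: the fraction of images whose per-image metric beats each
  threshold in a sweep (IoU counts a success when it exceeds the threshold,
  centroid distance when it falls below).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BBox",
    "DetectionEval",
    "SuccessCurve",
    "ComparisonSummary",
    "iou",
    "area_precision_recall",
    "centroid_distance",
    "success_curve",
    "compare_annotations",
    "DEFAULT_IOU_THRESHOLDS",
    "DEFAULT_CENTROID_THRESHOLDS",
]

#: Threshold sweeps used by default in success plots.
DEFAULT_IOU_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.91, 0.1), 10))
DEFAULT_CENTROID_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.01, 0.101, 0.01), 10))


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box: upper-left corner ``(x, y)``, width ``w``, height ``h``.

    ``x`` indexes columns and ``y`` rows.  Width and height must be strictly
    positive.  The centroid ``(x + w/2, y + h/2)`` is derived, never stored.
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box width/height must be positive, got w={self.w}, h={self.h}")

    @property
    def cx(self) -> float:
        return self.x + self.w / 2.0

    @property
    def cy(self) -> float:
        return self.y + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    def shift(self, dx: float, dy: float) -> "BBox":
        return BBox(self.x + dx, self.y + dy, self.w, self.h)

    def clip(self, image_w: float, image_h: float) -> "BBox":
        """Clip to image bounds, keeping width/height at least one pixel."""
        x1 = min(max(self.x, 0.0), image_w - 1.0)
        y1 = min(max(self.y, 0.0), image_h - 1.0)
        x2 = min(max(self.x2, x1 + 1.0), image_w)
        y2 = min(max(self.y2, y1 + 1.0), image_h)
        return BBox(x1, y1, x2 - x1, y2 - y1)

    def inside(self, image_w: float, image_h: float) -> bool:
        return self.x >= 0 and self.y >= 0 and self.x2 <= image_w and self.y2 <= image_h

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.w, self.h)


@dataclass(frozen=True)
class DetectionEval:
    """Per-image detection scores for one (ground truth, estimate) pair."""

    iou: float
    area_precision: float
    area_recall: float
    centroid_distance: float


@dataclass(frozen=True)
class SuccessCurve:
    """Success rates over a threshold sweep for one metric."""

    metric_name: str
    thresholds: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.rates):
            raise ValueError("thresholds and rates must have equal length")


@dataclass(frozen=True)
class ComparisonSummary:
    """Aggregate of per-image detection metrics: mean and population sd."""

    evals: tuple[DetectionEval, ...]
    mean: DetectionEval
    sd: DetectionEval


def _intersection_area(a: BBox, b: BBox) -> float:
    iw = min(a.x2, b.x2) - max(a.x, b.x)
    ih = min(a.y2, b.y2) - max(a.y, b.y)
    if iw <= 0 or ih <= 0:
        return 0.0
    return iw * ih


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    inter = _intersection_area(a, b)
    union = a.area + b.area - inter
    return inter / union


def area_precision_recall(pred: BBox, gt: BBox) -> tuple[float, float]:
    """Area-overlap precision and recall of a predicted box against the GT.

    precision = |pred ∩ gt| / |pred|, recall = |pred ∩ gt| / |gt|.  These are
    per-image area ratios (the natural reading when precision/recall are
    reported next to a per-image IoU), not dataset-level classification
    counts.
    """
    inter = _intersection_area(pred, gt)
    return inter / pred.area, inter / gt.area


def centroid_distance(gt: BBox, est: BBox, image_w: float, image_h: float) -> float:
    """Relative centroid error ``1/2 (|x_g - x_e|/W + |y_g - y_e|/H)``.

    ``(x_g, y_g)`` and ``(x_e, y_e)`` are the centroids of the ground-truth
    and estimated boxes; ``W`` and ``H`` are the image width and height.  The
    result is unitless; for boxes inside the image it is at most 1.
    """
    if image_w <= 0 or image_h <= 0:
        raise ValueError("image dimensions must be positive")
    return 0.5 * (abs(gt.cx - est.cx) / image_w + abs(gt.cy - est.cy) / image_h)


def evaluate_pair(gt: BBox, est: BBox, image_w: float, image_h: float) -> DetectionEval:
    """All four per-image metrics for one (ground truth, estimate) pair."""
    prec, rec = area_precision_recall(est, gt)
    return DetectionEval(
        iou=iou(gt, est),
        area_precision=prec,
        area_recall=rec,
        centroid_distance=centroid_distance(gt, est, image_w, image_h),
    )


def success_curve(
    evals: Sequence[DetectionEval],
    metric: str,
    thresholds: Sequence[float] | None = None,
) -> SuccessCurve:
    """Success rates over a threshold sweep.

    For ``metric="iou"`` an image succeeds at threshold ``t`` when its IoU is
    strictly greater than ``t``; for ``metric="centroid_distance"`` when its
    distance is strictly lower than ``t``.
    """
    if len(evals) == 0:
        raise ValueError("evals must be nonempty")
    if metric == "iou":
        values = np.array([e.iou for e in evals])
        thr = DEFAULT_IOU_THRESHOLDS if thresholds is None else tuple(thresholds)
        rates = tuple(float(np.mean(values > t)) for t in thr)
    elif metric == "centroid_distance":
        values = np.array([e.centroid_distance for e in evals])
        thr = DEFAULT_CENTROID_THRESHOLDS if thresholds is None else tuple(thresholds)
        rates = tuple(float(np.mean(values < t)) for t in thr)
    else:
        raise ValueError(f"unknown metric {metric!r}; expected 'iou' or 'centroid_distance'")
    if len(thr) == 0:
        raise ValueError("thresholds must be nonempty")
    return SuccessCurve(metric_name=metric, thresholds=tuple(float(t) for t in thr), rates=rates)


def compare_annotations(
    set_a: Sequence[BBox],
    set_b: Sequence[BBox],
    image_sizes: Sequence[tuple[float, float]] | tuple[float, float],
) -> ComparisonSummary:
    """Score annotation set B against set A (A is treated as ground truth).

    ``image_sizes`` is either one ``(W, H)`` pair applied to all images or a
    per-image sequence aligned with the box lists.  Returns the per-image
    evaluations plus the mean and population standard deviation of each
    metric.
    """
    if len(set_a) != len(set_b):
        raise ValueError(f"annotation sets differ in length: {len(set_a)} vs {len(set_b)}")
    if len(set_a) == 0:
        raise ValueError("annotation sets must be nonempty")
    if isinstance(image_sizes, tuple) and np.isscalar(image_sizes[0]):
        sizes: list[tuple[float, float]] = [image_sizes] * len(set_a)  # type: ignore[list-item]
    else:
        sizes = list(image_sizes)  # type: ignore[arg-type]
        if len(sizes) != len(set_a):
            raise ValueError("image_sizes must align with the annotation lists")
    evals = tuple(
        evaluate_pair(a, b, w, h) for a, b, (w, h) in zip(set_a, set_b, sizes)
    )
    arr = np.array(
        [[e.iou, e.area_precision, e.area_recall, e.centroid_distance] for e in evals]
    )
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)  # population sd, matching "mean of folds with the sd"
    return ComparisonSummary(
        evals=evals,
        mean=DetectionEval(*map(float, mean)),
        sd=DetectionEval(*map(float, sd)),
    )
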