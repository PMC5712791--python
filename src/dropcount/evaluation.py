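"""Detection scoring against ground truth.

Two complementary confusion modes are exposed: pixel-level (segmentation
quality, the mode behind the very small false-positive rates a large
background denominator produces) and object-level (droplet counting
quality, via greedy center matching). Counting accuracy itself is reported
as the relative error of detected vs manual counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import CircleSet


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    n_targets: int
    n_background: int = 0


@dataclass(frozen=True)
class DetectionRates:
    tpr: float
    fpr: float
    precision: float
    recall: float
    f_measure: float


def pixel_confusion(detected_map: np.ndarray, truth_map: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion; targets are truth-true pixels, background the rest."""
    detected_map = np.asarray(detected_map, dtype=bool)
    truth_map = np.asarray(truth_map, dtype=bool)
    if detected_map.shape != truth_map.shape:
        raise ValueError("detected and truth maps must have the same shape")
    tp = int(np.count_nonzero(detected_map & truth_map))
    fp = int(np.count_nonzero(detected_map & ~truth_map))
    fn = int(np.count_nonzero(~detected_map & truth_map))
    return ConfusionCounts(
        tp=tp,
        fp=fp,
        fn=fn,
        n_targets=int(np.count_nonzero(truth_map)),
        n_background=int(np.count_nonzero(~truth_map)),
    )


def object_confusion(detected: CircleSet, truth: CircleSet) -> ConfusionCounts:
    """Greedy one-to-one circle matching in ascending center-distance order.

    A detection may match an unmatched truth circle iff its center lies
    within that circle's radius. Equidistant ties are broken by the (row,
    col) ordering both sets already carry.
    """
    pairs = []
    for di, d in enumerate(detected):
        for ti, t in enumerate(truth):
            dist = d.center_distance(t)
            if dist <= t.radius:
                pairs.append((dist, di, ti))
    pairs.sort()
    det_used = [False] * len(detected)
    truth_used = [False] * len(truth)
    tp = 0
    for _, di, ti in pairs:
        if not det_used[di] and not truth_used[ti]:
            det_used[di] = True
            truth_used[ti] = True
            tp += 1
    return ConfusionCounts(
        tp=tp,
        fp=len(detected) - tp,
        fn=len(truth) - tp,
        n_targets=len(truth),
        n_background=0,
    )


def rates_and_f(counts: ConfusionCounts) -> DetectionRates:
    """TPR, FPR, precision, recall and the F-measure (harmonic mean).

    FPR is NaN when no background denominator is defined (object mode);
    F is 0 when precision + recall is 0.
    """
    if counts.n_targets <= 0:
        raise ValueError("no ground-truth targets: rates undefined")
    tpr = counts.tp / counts.n_targets
    fpr = counts.fp / counts.n_background if counts.n_background > 0 else float("nan")
    denom_p = counts.tp + counts.fp
    precision = counts.tp / denom_p if denom_p > 0 else 0.0
    recall = counts.tp / (counts.tp + counts.fn)
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return DetectionRates(tpr=tpr, fpr=fpr, precision=precision, recall=recall, f_measure=f)


def roc_curve(
    enhanced: np.ndarray,
    truth_map: np.ndarray,
    thresholds: Sequence[float] | None = None,
) -> tuple[np.ndarray, float]:
    """Pixel-level ROC by sweeping the binarization threshold on image J.

    Returns ``(points, auc)`` where points is an (n, 2) array of (FPR, TPR)
    sorted by FPR and anchored at (0, 0) and (1, 1); AUC by the trapezoid
    rule.
    """
    truth_map = np.asarray(truth_map, dtype=bool)
    if not truth_map.any() or truth_map.all():
        raise ValueError("degenerate truth: both classes required for a ROC")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size < 2:
        raise ValueError("at least two thresholds required")
    pts = [(0.0, 0.0), (1.0, 1.0)]
    for t in thresholds:
        c = pixel_confusion(np.asarray(enhanced) > t, truth_map)
        pts.append((c.fp / c.n_background, c.tp / c.n_targets))
    points = np.array(sorted(pts))
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return points, auc


def relative_error(true_count: int, detected_count: int) -> float:
    """Counting relative error, percent: 100*|true - detected|/true (2 dp)."""
    if true_count <= 0:
        raise ValueError("true count must be positive")
    return round(100.0 * abs(true_count - detected_count) / true_count, 2)
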