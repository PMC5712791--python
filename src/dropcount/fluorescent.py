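"""Fluorescent micro-droplet extraction.

Occupied droplets are much brighter than empty ones, so they are segmented
by a single global threshold; because absolute brightness varies between
acquisitions, the threshold is tied to the image's mean intensity m by the
fitted affine law D(m) = 1.3717*m + 0.0126 (on the [0, 1] intensity scale),
clipped at 1. A second Hough pass then counts the segmented bright spots.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .enhance import gaussian_denoise
from .hough import detect_circles_in_mask
from .segment import binarize, morphological_open
from .types import Circle, CircleSet


def fluorescent_threshold(
    m: float, slope: float = 1.3717, intercept: float = 0.0126
) -> float:
    """Mean-intensity-adaptive segmentation threshold D(m), clipped to <= 1."""
    if not 0 <= m <= 1:
        raise ValueError("mean intensity must be in [0, 1]")
    return min(slope * m + intercept, 1.0)


def detect_fluorescent(
    image: np.ndarray, config: PipelineConfig | None = None
) -> CircleSet:
    """Detect the bright (occupied) droplet subset.

    m is taken on the Gaussian-denoised image I — the normalized filter
    leaves the mean essentially unchanged while stabilizing it against shot
    noise — and I is binarized at D(m), opened with the same element as the
    overall segmentation, then passed to the Hough counter.
    """
    config = config or PipelineConfig()
    denoised = gaussian_denoise(image, config.gaussian_sigma)
    m = float(denoised.mean())
    d = fluorescent_threshold(m, config.threshold_slope, config.threshold_intercept)
    mask = morphological_open(binarize(denoised, d), config.opening_radius)
    return detect_circles_in_mask(mask, config)


def label_overall_circles(overall: CircleSet, fluorescent: CircleSet) -> CircleSet:
    """Merge the two passes into one labeled set.

    An overall circle is flagged fluorescent iff some fluorescent-pass
    center falls inside it (center distance <= its radius); fluorescent-pass
    circles matching no overall circle are appended, so the merged counts
    always satisfy n_fluorescent <= n_overall.
    """
    flags = []
    matched = [False] * len(fluorescent)
    for c in overall:
        hit = False
        for j, f in enumerate(fluorescent):
            if c.center_distance(f) <= c.radius:
                hit = True
                matched[j] = True
        flags.append(hit)
    merged = [
        Circle(c.row, c.col, c.radius, c.score, fluorescent=flag)
        for c, flag in zip(overall, flags)
    ]
    for j, f in enumerate(fluorescent):
        if not matched[j]:
            merged.append(Circle(f.row, f.col, f.radius, f.score, fluorescent=True))
    return CircleSet(merged)
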