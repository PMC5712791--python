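"""End-to-end per-image analysis: counts, occupancy and concentration."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .concentration import concentration_from_counts
from .config import PipelineConfig
from .fluorescent import detect_fluorescent, label_overall_circles
from .hough import detect_overall
from .types import CircleSet


@dataclass
class DetectionSummary:
    """Per-image detection result with the Poisson concentration readout.

    ``lam`` and ``concentration_fM`` are None when the readout is undefined
    (no droplets, or a saturated frame with every droplet fluorescent).
    """

    circles: CircleSet
    n_overall: int
    n_fluorescent: int
    p_occupied: float | None
    lam: float | None
    concentration_fM: float | None

    def to_dict(self) -> dict:
        return {
            "n_overall": self.n_overall,
            "n_fluorescent": self.n_fluorescent,
            "p_occupied": self.p_occupied,
            "lambda": self.lam,
            "concentration_fM": self.concentration_fM,
        }


def analyze_image(
    image: np.ndarray, config: PipelineConfig | None = None
) -> DetectionSummary:
    """Run both detection passes and the concentration conversion."""
    config = config or PipelineConfig()
    overall = detect_overall(image, config)
    fluor = detect_fluorescent(image, config)
    merged = label_overall_circles(overall, fluor)
    n_overall = len(merged)
    n_fluor = merged.n_fluorescent
    if n_overall == 0 or n_fluor >= n_overall:
        return DetectionSummary(
            circles=merged,
            n_overall=n_overall,
            n_fluorescent=n_fluor,
            p_occupied=(n_fluor / n_overall) if n_overall else None,
            lam=None,
            concentration_fM=None,
        )
    result = concentration_from_counts(
        n_fluor, n_overall, config.droplet_diameter_um, config.avogadro
    )
    return DetectionSummary(
        circles=merged,
        n_overall=n_overall,
        n_fluorescent=n_fluor,
        p_occupied=result.p_occupied,
        lam=result.lam,
        concentration_fM=result.c_fM,
    )
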