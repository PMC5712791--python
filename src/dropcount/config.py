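"""Pipeline configuration with the method's published operating point.

Defaults: Gaussian sigma 1 px, CLAHE with 8x8 tiles and clip fraction 0.05,
Hough search radii 16-32 px, droplet diameter 30 um. The Avogadro constant
defaults to the truncated 6.02e23 mol^-1 used by the assay's reference
arithmetic (see docs/methods.md); it is overridable for full-precision work.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    gaussian_sigma: float = 1.0
    clahe_tiles: int = 8
    clahe_clip: float = 0.05
    opening_radius: int = 5
    radius_min: int = 16
    radius_max: int = 32
    hough_sensitivity: float = 0.33
    droplet_diameter_um: float = 30.0
    avogadro: float = 6.02e23
    threshold_slope: float = 1.3717
    threshold_intercept: float = 0.0126
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if self.radius_min > self.radius_max:
            raise ValueError(
                f"radius_min ({self.radius_min}) > radius_max ({self.radius_max})"
            )
        if self.radius_min < 1:
            raise ValueError("radius_min must be >= 1")
        if not 0 < self.clahe_clip <= 1:
            raise ValueError("clahe_clip must be in (0, 1]")
        if self.clahe_tiles < 1:
            raise ValueError("clahe_tiles must be >= 1")
        if not 0 < self.hough_sensitivity <= 1:
            raise ValueError("hough_sensitivity must be in (0, 1]")
        if self.droplet_diameter_um <= 0:
            raise ValueError("droplet_diameter_um must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig`, optionally overriding defaults.

    ``path`` may be None (pure defaults) or a JSON file with a flat object
    whose keys are PipelineConfig field names; unknown keys are rejected.
    """
    if path is None:
        return PipelineConfig()
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a JSON object")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return PipelineConfig(**raw)
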