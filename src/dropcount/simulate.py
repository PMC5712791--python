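"""Synthetic fluorescent micro-droplet image (FMI) generator.

Emulates the features that make real droplet frames hard: a dense packing
of touching-but-not-merging round droplets of similar radius, weakly
luminescent empty droplets barely above background, bright occupied
droplets, small bright speckle/vesicle distractors, and mixed
Poisson-Gaussian sensor noise. Occupancy is drawn per droplet as
k ~ Poisson(lambda); a droplet is fluorescent iff k >= 1, so simulated
scenes obey the same occupancy law the concentration readout inverts.

Ground truth (circle list with occupancy flags, plus rasterized masks) is
recorded exactly, playing the role that expert manual annotation plays for
real frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .concentration import fluorescent_fraction_expected  # noqa: F401  (re-export)
from .types import Circle, CircleSet

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_fmi",
    "sample_layout",
    "rasterize_disks",
    "fluorescent_fraction_expected",
]


@dataclass
class SimulationParams:
    """Scene and noise parameters for one synthetic frame.

    Droplets are near-monodisperse: truth radii are drawn uniformly from
    ``radius_range`` (default 18-28 px, centered on the ~24 px nominal
    droplet radius), leaving margin inside the detector's 16-32 px search
    band for the ~1 px apparent dilation that soft edges, denoising and
    thresholding add to a droplet's segmented radius.

    Intensity levels are on the [0, 1] scale. ``empty_intensity`` sits just
    above background: empty droplets are weakly luminescent (stray enzyme),
    which is the hard case the enhancement stage exists for, while staying
    below the mean-adaptive fluorescent threshold D(m) at realistic fill
    fractions (see docs/methods.md). ``photon_scale`` is the photon count
    corresponding to intensity 1.0 in the Poisson shot-noise model.
    """

    height: int = 1080
    width: int = 1920
    n_droplets: int = 200
    radius_range: tuple[int, int] = (18, 28)
    lambda_occupancy: float = 0.14
    empty_intensity: float = 0.09
    fluorescent_intensity: float = 0.7
    background_level: float = 0.05
    gaussian_noise_sd: float = 0.02
    photon_scale: float = 500.0
    n_speckles: int = 30
    speckle_intensity: float = 0.8
    max_overlap: float = 2.0
    edge_softness: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] < 1:
            raise ValueError("invalid radius_range")
        if not (
            0 <= self.background_level < self.empty_intensity < self.fluorescent_intensity <= 1
        ):
            raise ValueError(
                "need background_level < empty_intensity < fluorescent_intensity in [0, 1]"
            )
        if self.lambda_occupancy < 0:
            raise ValueError("lambda_occupancy must be >= 0")
        if self.n_droplets < 0 or self.n_speckles < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class GroundTruth:
    """Exact simulation truth for one frame."""

    circles: CircleSet
    mask_overall: np.ndarray
    mask_fluorescent: np.ndarray
    occupancy: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_overall(self) -> int:
        return len(self.circles)

    @property
    def n_fluorescent(self) -> int:
        return self.circles.n_fluorescent


def sample_layout(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[list[tuple[int, int, int]], np.ndarray]:
    """Place droplets by rejection sampling and draw per-droplet occupancy.

    Returns ``(centers, k)`` where centers are (row, col, radius) fully
    inside the frame with pairwise center distance >= r_i + r_j -
    max_overlap (droplets may touch, never merge), and k[i] ~
    Poisson(lambda_occupancy) is the number of encapsulated nanoparticles.
    """
    rmin, rmax = params.radius_range
    placed: list[tuple[int, int, int]] = []
    budget = 300 * max(params.n_droplets, 1)
    attempts = 0
    while len(placed) < params.n_droplets:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {params.n_droplets} droplets of radius "
                f"{rmin}-{rmax} in a {params.height}x{params.width} frame "
                f"after {budget} attempts: packing infeasible"
            )
        attempts += 1
        r = int(rng.integers(rmin, rmax + 1))
        if params.height <= 2 * r or params.width <= 2 * r:
            continue
        row = int(rng.integers(r, params.height - r))
        col = int(rng.integers(r, params.width - r))
        ok = True
        for pr, pc, prad in placed:
            if (row - pr) ** 2 + (col - pc) ** 2 < (r + prad - params.max_overlap) ** 2:
                ok = False
                break
        if ok:
            placed.append((row, col, r))
    k = rng.poisson(params.lambda_occupancy, size=len(placed))
    return placed, k


def rasterize_disks(
    shape: tuple[int, int], circles: list[tuple[int, int, int]]
) -> np.ndarray:
    """Boolean union of the disks (dist <= r) over the given frame shape."""
    mask = np.zeros(shape, dtype=bool)
    for row, col, r in circles:
        r0, r1 = max(row - r, 0), min(row + r + 1, shape[0])
        c0, c1 = max(col - r, 0), min(col + r + 1, shape[1])
        yy, xx = np.ogrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] |= (yy - row) ** 2 + (xx - col) ** 2 <= r**2
    return mask


def _stamp_disk(
    image: np.ndarray,
    row: int,
    col: int,
    radius: float,
    level: float,
    background: float,
    softness: float,
) -> None:
    """Max-composite one soft-edged disk onto the image in place."""
    r_ext = int(np.ceil(radius + softness))
    r0, r1 = max(row - r_ext, 0), min(row + r_ext + 1, image.shape[0])
    c0, c1 = max(col - r_ext, 0), min(col + r_ext + 1, image.shape[1])
    yy, xx = np.ogrid[r0:r1, c0:c1]
    dist = np.hypot(yy - row, xx - col)
    alpha = np.clip((radius - dist) / softness + 0.5, 0.0, 1.0)
    patch = image[r0:r1, c0:c1]
    np.maximum(patch, background + alpha * (level - background), out=patch)


def generate_fmi(params: SimulationParams) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic frame with its exact ground truth.

    Deterministic for a fixed ``params`` (including its seed).
    """
    rng = np.random.default_rng(params.seed)
    centers, k = sample_layout(params, rng)
    fluorescent = k >= 1

    image = np.full((params.height, params.width), params.background_level)
    for (row, col, r), occ in zip(centers, fluorescent):
        level = params.fluorescent_intensity if occ else params.empty_intensity
        _stamp_disk(
            image, row, col, r, level, params.background_level, params.edge_softness
        )
    for _ in range(params.n_speckles):
        r = float(rng.uniform(2.0, 4.0))
        row = int(rng.integers(0, params.height))
        col = int(rng.integers(0, params.width))
        _stamp_disk(
            image,
            row,
            col,
            r,
            params.speckle_intensity,
            params.background_level,
            params.edge_softness,
        )

    if params.photon_scale > 0:
        image = rng.poisson(image * params.photon_scale) / params.photon_scale
    if params.gaussian_noise_sd > 0:
        image = image + rng.normal(0.0, params.gaussian_noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    shape = (params.height, params.width)
    truth = GroundTruth(
        circles=CircleSet(
            [
                Circle(row=float(r_), col=float(c_), radius=float(rad), fluorescent=bool(f))
                for (r_, c_, rad), f in zip(centers, fluorescent)
            ]
        ),
        mask_overall=rasterize_disks(shape, centers),
        mask_fluorescent=rasterize_disks(
            shape, [c for c, f in zip(centers, fluorescent) if f]
        ),
        occupancy=np.asarray(k, dtype=int),
    )
    return image, truth
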