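"""Poisson-occupancy readout: droplet counts -> molar concentration.

Nanoparticles are delivered to the droplet-generation nozzle at random, so
the number k encapsulated per droplet is Poisson with mean lambda. A droplet
is fluorescent iff k >= 1, hence

    P(occupied) = n_fluorescent / n_overall = 1 - exp(-lambda)
    lambda      = -ln(1 - p)

lambda is the mean number of particles per droplet; dividing by Avogadro's
number gives moles per droplet, and dividing by the droplet volume gives the
concentration, reported in femtomolar (1 fM = 1e-15 mol/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

AVOGADRO_DEFAULT = 6.02e23


@dataclass(frozen=True)
class ConcentrationResult:
    n_overall: int
    n_fluorescent: int
    p_occupied: float
    lam: float
    n_moles: float
    volume_L: float
    c_fM: float

    def to_dict(self) -> dict:
        return {
            "n_overall": self.n_overall,
            "n_fluorescent": self.n_fluorescent,
            "p_occupied": self.p_occupied,
            "lambda": self.lam,
            "moles_per_droplet": self.n_moles,
            "droplet_volume_L": self.volume_L,
            "concentration_fM": self.c_fM,
        }


def poisson_pmf(k: int, lam: float) -> float:
    """P(K = k) for K ~ Poisson(lam)."""
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        return 1.0 if k == 0 else 0.0
    return math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))


def lambda_from_counts(n_fluorescent: int, n_overall: int) -> float:
    """Invert the occupancy fraction: lambda = -ln(1 - f/t).

    Raises on a saturated plate (every droplet fluorescent): the assay is
    then outside its dynamic range and lambda is unbounded.
    """
    if n_overall <= 0:
        raise ValueError("n_overall must be positive")
    if not 0 <= n_fluorescent <= n_overall:
        raise ValueError("need 0 <= n_fluorescent <= n_overall")
    if n_fluorescent == n_overall:
        raise ValueError(
            "all droplets fluorescent: occupancy saturated, lambda undefined"
        )
    return -math.log1p(-n_fluorescent / n_overall)


def fluorescent_fraction_expected(lam: float) -> float:
    """Expected fluorescent fraction 1 - exp(-lambda) (inverse of the above)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return -math.expm1(-lam)


def droplet_volume_liters(diameter_um: float) -> float:
    """Volume of a spherical droplet of the given diameter, in liters."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    radius_m = diameter_um * 1e-6 / 2
    volume_m3 = 4.0 / 3.0 * math.pi * radius_m**3
    return volume_m3 * 1000.0  # m^3 -> L


def concentration_fM(
    lam: float, volume_L: float, avogadro: float = AVOGADRO_DEFAULT
) -> float:
    """Concentration in femtomolar from mean occupancy and droplet volume."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if volume_L <= 0:
        raise ValueError("volume must be positive")
    moles = lam / avogadro
    return moles / volume_L * 1e15


def concentration_from_counts(
    n_fluorescent: int,
    n_overall: int,
    diameter_um: float = 30.0,
    avogadro: float = AVOGADRO_DEFAULT,
) -> ConcentrationResult:
    """Full counts -> fM pipeline, returning every intermediate quantity."""
    lam = lambda_from_counts(n_fluorescent, n_overall)
    volume = droplet_volume_liters(diameter_um)
    return ConcentrationResult(
        n_overall=n_overall,
        n_fluorescent=n_fluorescent,
        p_occupied=n_fluorescent / n_overall,
        lam=lam,
        n_moles=lam / avogadro,
        volume_L=volume,
        c_fM=concentration_fM(lam, volume, avogadro),
    )
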