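"""Poisson occupancy model for single-cell limiting dilution.

When a homogenized cell suspension is distributed across the wells of a
microplate, the number of cells landing in each well is well described by a
Poisson distribution with intensity ``lam`` (expected cells per well).  The
blank fraction after incubation estimates ``exp(-lam)``, which lets a bench
scientist pick a dilution level so that most occupied wells started from a
single cell, and to re-calibrate ``lam`` from an observed plate census.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PlateSpec",
    "OccupancyModel",
    "AbundanceProfile",
    "SeedingPlan",
    "LambdaCalibration",
    "occupancy_pmf",
    "density_for_blank_fraction",
    "calibrate_lambda",
    "dilution_acceptable",
    "purity_given_growth",
    "plan_dilution_series",
]

#: Default acceptance band for the observed blank fraction of a pilot plate.
#: A plate within this band is considered correctly diluted for single-cell work.
DEFAULT_BLANK_BAND = (0.24, 0.30)

_TAIL_MASS = 1e-12  # Poisson series truncation: stop once tail mass < this


@dataclass(frozen=True)
class PlateSpec:
    """A microplate geometry: number of wells and fill volume per well (µL)."""

    n_wells: int = 384
    well_volume_ul: float = 60.0

    def __post_init__(self) -> None:
        if self.n_wells <= 0:
            raise ValueError(f"n_wells must be positive, got {self.n_wells}")
        if self.well_volume_ul <= 0:
            raise ValueError(
                f"well_volume_ul must be positive, got {self.well_volume_ul}"
            )

    @property
    def well_volume_ml(self) -> float:
        return self.well_volume_ul / 1000.0


@dataclass(frozen=True)
class OccupancyModel:
    """Poisson model for cells-per-well with intensity ``lam`` (cells/well)."""

    lam: float

    def __post_init__(self) -> None:
        if self.lam < 0 or not math.isfinite(self.lam):
            raise ValueError(f"lam must be finite and >= 0, got {self.lam}")

    def pmf(self, k: int) -> float:
        return occupancy_pmf(self, k)

    def blank_fraction(self) -> float:
        """Expected fraction of wells that receive no cell, exp(-lam)."""
        return math.exp(-self.lam)


@dataclass(frozen=True)
class AbundanceProfile:
    """Relative abundances of the strains present in the inoculum."""

    labels: tuple[str, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.proportions):
            raise ValueError("labels and proportions must have equal length")
        p = np.asarray(self.proportions, dtype=float)
        if (p < 0).any():
            raise ValueError("proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")

    @classmethod
    def from_proportions(cls, proportions: Sequence[float]) -> "AbundanceProfile":
        labels = tuple(f"strain_{i + 1}" for i in range(len(proportions)))
        return cls(labels=labels, proportions=tuple(float(p) for p in proportions))


@dataclass(frozen=True)
class LambdaCalibration:
    """Estimated seeding intensity with a confidence interval.

    The interval comes from the exact (Clopper-Pearson) binomial interval on
    the blank fraction, mapped through ``lam = -ln(blank_fraction)``.  Because
    the map is decreasing, the upper proportion bound gives the lower lam
    bound and vice versa.
    """

    lam: float
    lam_low: float
    lam_high: float
    n_blank: int
    n_wells: int
    confidence: float = 0.95

    @property
    def model(self) -> OccupancyModel:
        return OccupancyModel(self.lam)


@dataclass(frozen=True)
class SeedingPlan:
    """A dilution plan that hits a target blank fraction on a given plate."""

    target_blank_fraction: float
    lam: float
    density_cfu_per_ml: float
    dilution_steps: tuple[float, ...]
    plate: PlateSpec = field(default_factory=PlateSpec)

    def __post_init__(self) -> None:
        # exp(-lam) underflows to 0 for very dense seeding, hence >= 0
        if not (0.0 <= self.target_blank_fraction < 1.0):
            raise ValueError("target_blank_fraction must be in [0, 1)")
        if abs(math.exp(-self.lam) - self.target_blank_fraction) > 1e-12:
            raise ValueError("lam inconsistent with target_blank_fraction")
        expected = self.lam / self.plate.well_volume_ml
        if not math.isclose(self.density_cfu_per_ml, expected, rel_tol=1e-9):
            raise ValueError("density inconsistent with lam and well volume")

    def total_dilution(self) -> float:
        return float(np.prod(self.dilution_steps)) if self.dilution_steps else 1.0


def occupancy_pmf(model: OccupancyModel | float, k: int) -> float:
    """Probability that a well receives exactly ``k`` cells.

    P(X = k) = exp(-lam) * lam**k / k!
    """
    lam = model.lam if isinstance(model, OccupancyModel) else float(model)
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if k < 0 or int(k) != k:
        raise ValueError(f"k must be a non-negative integer, got {k}")
    return float(stats.poisson.pmf(int(k), lam))


def density_for_blank_fraction(p0: float, plate: PlateSpec) -> float:
    """Cell density (CFU/mL) that yields blank fraction ``p0`` on ``plate``.

    Inverts the Poisson zero class: lam = -ln(p0), density = lam / V_well(mL).
    E.g. a 24.3% target on a 384-well plate at 60 µL/well asks for
    -ln(0.243)/0.060 ≈ 23.6 CFU/mL, i.e. ~24 CFU/mL at bench precision.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must lie strictly in (0, 1), got {p0}")
    lam = -math.log(p0)
    return lam / plate.well_volume_ml


def calibrate_lambda(
    n_blank: int, n_wells: int, confidence: float = 0.95
) -> LambdaCalibration:
    """Estimate the seeding intensity from a plate census.

    lam_hat = -ln(n_blank / n_wells); the confidence interval is the
    Clopper-Pearson (exact beta) interval on the blank proportion pushed
    through -ln.  ``n_blank == 0`` leaves lam unidentifiable (every dilution
    large enough to blank no well is consistent) and raises.
    """
    if not (0 < n_blank <= n_wells):
        raise ValueError(
            f"need 0 < n_blank <= n_wells, got n_blank={n_blank}, n_wells={n_wells}"
        )
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    phat = n_blank / n_wells
    lam_hat = -math.log(phat)
    alpha = 1.0 - confidence
    # Clopper-Pearson bounds on the blank proportion
    p_low = (
        0.0 if n_blank == 0 else float(stats.beta.ppf(alpha / 2, n_blank, n_wells - n_blank + 1))
    )
    if n_blank == n_wells:
        p_high = 1.0
    else:
        p_high = float(stats.beta.ppf(1 - alpha / 2, n_blank + 1, n_wells - n_blank))
    lam_low = -math.log(p_high)  # -ln is decreasing
    lam_high = math.inf if p_low == 0.0 else -math.log(p_low)
    return LambdaCalibration(
        lam=lam_hat,
        lam_low=lam_low,
        lam_high=lam_high,
        n_blank=n_blank,
        n_wells=n_wells,
        confidence=confidence,
    )


def dilution_acceptable(
    blank_fraction: float,
    low: float = DEFAULT_BLANK_BAND[0],
    high: float = DEFAULT_BLANK_BAND[1],
) -> bool:
    """Whether an observed blank fraction falls in the acceptance band.

    Bounds are inclusive; the default band 0.24-0.30 is the conventional
    single-cell dilution window.
    """
    if not (0.0 <= blank_fraction <= 1.0):
        raise ValueError(f"blank_fraction must be in [0, 1], got {blank_fraction}")
    return low <= blank_fraction <= high


def purity_given_growth(
    model: OccupancyModel | float, profile: AbundanceProfile | Sequence[float]
) -> float:
    """Probability an occupied well is a pure (single-strain) culture.

    Conditioned on at least one cell, the well is pure when all of its k
    cells drew the same strain from the abundance profile:

        P(pure | k >= 1) = sum_{k>=1} pmf(k) * sum_i p_i^k / (1 - pmf(0))

    The Poisson series is truncated once the remaining tail mass drops below
    1e-12, which bounds the truncation error at that level.
    """
    lam = model.lam if isinstance(model, OccupancyModel) else float(model)
    if lam <= 0:
        raise ValueError("lam must be > 0: purity is conditioned on occupied wells")
    if not isinstance(profile, AbundanceProfile):
        profile = AbundanceProfile.from_proportions(list(profile))
    p = np.asarray(profile.proportions, dtype=float)

    total = 0.0
    cum = math.exp(-lam)  # mass at k=0, excluded from the sum
    k = 1
    while cum < 1.0 - _TAIL_MASS:
        pk = float(stats.poisson.pmf(k, lam))
        total += pk * float(np.sum(p**k))
        cum += pk
        k += 1
        if k > 10_000:  # safety stop; unreachable for sane lam
            break
    return total / (1.0 - math.exp(-lam))


def plan_dilution_series(
    stock_cfu_per_ml: float,
    target_cfu_per_ml: float,
    max_step: float = 10.0,
    plate: PlateSpec | None = None,
) -> SeedingPlan:
    """Decompose stock -> target into serial dilution steps, largest first.

    Greedy: take ``max_step``-fold dilutions while the remaining ratio allows,
    then one final fractional step.  The product of the steps equals
    stock/target to within 1e-9 relative.
    """
    if target_cfu_per_ml <= 0:
        raise ValueError("target density must be positive")
    if stock_cfu_per_ml < target_cfu_per_ml:
        raise ValueError(
            f"stock ({stock_cfu_per_ml}) must be >= target ({target_cfu_per_ml})"
        )
    if max_step <= 1:
        raise ValueError("max_step must exceed 1")
    plate = plate or PlateSpec()

    ratio = stock_cfu_per_ml / target_cfu_per_ml
    steps: list[float] = []
    remaining = ratio
    while remaining > max_step * (1 + 1e-12):
        steps.append(max_step)
        remaining /= max_step
    if remaining > 1 + 1e-12:
        steps.append(remaining)

    lam = target_cfu_per_ml * plate.well_volume_ml
    return SeedingPlan(
        target_blank_fraction=math.exp(-lam),
        lam=lam,
        density_cfu_per_ml=target_cfu_per_ml,
        dilution_steps=tuple(steps),
        plate=plate,
    )
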