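"""Synthetic inputs for every pipeline stage.

Three generators mirror the data the analysis modules consume:

* Poisson-seeded plates — per-well cell counts from a Poisson(lam) draw,
  strain identities from a multinomial abundance profile, and per-cell
  Bernoulli growth thinning (so the effective seeding intensity is
  ``lam * growth_prob``, by Poisson thinning).  OD values are a two-level
  constant (blank baseline vs occupied signal), which is all the growth
  caller needs.
* DOE run responses — the true quadratic surface evaluated on a design plus
  iid Gaussian noise.
* Tension curves — piecewise-linear-in-log10 tension with a known breakpoint
  plus Gaussian noise.

Every generator takes an explicit seed, drives a single private
``numpy.random.Generator``, and is bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .activity import TensionCurve
from .design import DesignMatrix
from .doe_rsm import QuadraticModel
from .plate_screening import WellRecord
from .plate_seeding import AbundanceProfile, PlateSpec

__all__ = [
    "PlateSimConfig",
    "PlateSimResult",
    "SurfaceSimConfig",
    "simulate_plate",
    "simulate_responses",
    "simulate_tension_curve",
]

DEFAULT_BLANK_OD = 0.04
DEFAULT_SIGNAL_OD = 0.5


@dataclass(frozen=True)
class PlateSimConfig:
    plate: PlateSpec
    lam: float
    profile: AbundanceProfile
    growth_prob: float = 1.0
    seed: int = 0
    blank_od: float = DEFAULT_BLANK_OD
    signal_od: float = DEFAULT_SIGNAL_OD

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not (0.0 <= self.growth_prob <= 1.0):
            raise ValueError("growth_prob must be in [0, 1]")


@dataclass(frozen=True)
class PlateSimResult:
    """Per-well outcome of a simulated seeding + growth experiment."""

    config: PlateSimConfig
    strain_counts: np.ndarray  # (n_wells, n_strains) surviving cells
    od600: np.ndarray

    @property
    def cells_per_well(self) -> np.ndarray:
        return self.strain_counts.sum(axis=1)

    @property
    def occupied(self) -> np.ndarray:
        return self.cells_per_well > 0

    @property
    def blank_fraction(self) -> float:
        return float(1.0 - self.occupied.mean())

    @property
    def n_blank(self) -> int:
        return int((~self.occupied).sum())

    def purity_fraction(self) -> float:
        """Fraction of occupied wells whose surviving cells are one strain."""
        occ = self.occupied
        if not occ.any():
            raise ValueError("no occupied wells: purity undefined")
        pure = (self.strain_counts[occ] == self.cells_per_well[occ][:, None]).any(axis=1)
        return float(pure.mean())

    def strain_mix_fractions(self) -> tuple[float, float, float]:
        """(pure, two-strain, >2-strain) fractions among occupied wells."""
        occ = self.strain_counts[self.occupied]
        n_strains_present = (occ > 0).sum(axis=1)
        n = len(occ)
        return (
            float((n_strains_present == 1).sum() / n),
            float((n_strains_present == 2).sum() / n),
            float((n_strains_present > 2).sum() / n),
        )

    def to_well_records(self) -> list[WellRecord]:
        """WellRecords with synthetic plate coordinates W0001, W0002, ..."""
        occ = self.occupied
        return [
            WellRecord(
                well_id=f"W{i + 1:04d}",
                od600=float(od),
                growth=bool(g),
            )
            for i, (od, g) in enumerate(zip(self.od600, occ))
        ]


def simulate_plate(config: PlateSimConfig) -> PlateSimResult:
    """Seed a plate: Poisson counts, multinomial strains, Bernoulli growth.

    Strain identities are drawn by sequential binomial splitting of each
    well's surviving count across the profile (equivalent to per-cell
    categorical draws, but vectorized across wells).
    """
    rng = np.random.default_rng(config.seed)
    n_wells = config.plate.n_wells
    p = np.asarray(config.profile.proportions, dtype=float)
    n_strains = p.size

    deposited = rng.poisson(config.lam, size=n_wells)
    surviving = (
        rng.binomial(deposited, config.growth_prob)
        if config.growth_prob < 1.0
        else deposited
    )

    strain_counts = np.zeros((n_wells, n_strains), dtype=np.int64)
    remaining = surviving.copy()
    remaining_p = 1.0
    for j in range(n_strains - 1):
        if remaining_p <= 0:
            break
        frac = min(max(p[j] / remaining_p, 0.0), 1.0)
        draw = rng.binomial(remaining, frac)
        strain_counts[:, j] = draw
        remaining = remaining - draw
        remaining_p -= p[j]
    strain_counts[:, n_strains - 1] = remaining

    od600 = np.where(
        strain_counts.sum(axis=1) > 0, config.signal_od, config.blank_od
    ).astype(float)
    return PlateSimResult(config=config, strain_counts=strain_counts, od600=od600)


@dataclass(frozen=True)
class SurfaceSimConfig:
    true_model: QuadraticModel
    design: DesignMatrix
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_responses(config: SurfaceSimConfig) -> np.ndarray:
    """Per-run responses: true surface + iid Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    mean = np.atleast_1d(config.true_model.predict(config.design.coded))
    if config.noise_sd == 0:
        return mean.copy()
    return mean + rng.normal(0.0, config.noise_sd, size=mean.shape)


def simulate_tension_curve(
    cmc: float,
    slope: float,
    plateau: float,
    n_points: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    span_decades: float = 1.5,
) -> TensionCurve:
    """Tension curve with a known breakpoint.

    Concentrations are log-spaced over ``span_decades`` decades either side
    of the CMC; tension follows ``plateau + slope * min(log10 c - log10 cmc, 0)``
    plus Gaussian noise.  ``slope`` is in mN/m per decade and must be
    negative (tension falls toward the CMC); ``plateau`` is the post-CMC
    tension in mN/m.
    """
    if cmc <= 0:
        raise ValueError("cmc must be positive")
    if slope >= 0:
        raise ValueError("pre-break slope must be negative (tension decreases)")
    if plateau <= 0:
        raise ValueError("plateau tension must be positive")
    if n_points < 5:
        raise ValueError("need at least 5 points for a usable curve")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.linspace(np.log10(cmc) - span_decades, np.log10(cmc) + span_decades, n_points)
    tension = plateau + slope * np.minimum(x - np.log10(cmc), 0.0)
    if noise_sd > 0:
        tension = tension + rng.normal(0.0, noise_sd, size=n_points)
    return TensionCurve(
        concentrations=tuple(10.0**x), tensions=tuple(float(t) for t in tension)
    )
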