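"""Surfactant-activity statistics: tension-reduction tests and CMC estimation.

A culture supernatant is called surfactant-active when its surface tension is
significantly *below* the medium control (two-sided equal-variance t test,
with a one-directional decision gate: a significant increase is not
activity).  The critical micelle concentration (CMC) is read from a
tension-vs-concentration curve as the breakpoint of a continuous two-segment
model in log10 concentration — linearly decreasing below the breakpoint,
flat at the plateau above it, the classic shape of a surfactant titration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "TensionMeasurement",
    "TensionCurve",
    "CMCEstimate",
    "ActivityResult",
    "CMCEstimator",
    "flag_active",
    "estimate_cmc",
]


@dataclass(frozen=True)
class TensionMeasurement:
    """Replicate surface-tension readings (mN/m) for one sample."""

    sample_id: str
    replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValueError("at least one replicate required")
        for v in self.replicates:
            if not (0.0 < v < 100.0):
                raise ValueError(
                    f"surface tension {v} mN/m outside the physical range (0, 100)"
                )

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))


@dataclass(frozen=True)
class TensionCurve:
    """Surface tension (mN/m) vs surfactant concentration (mg/mL)."""

    concentrations: tuple[float, ...]
    tensions: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        t = np.asarray(self.tensions, dtype=float)
        if c.shape != t.shape or c.ndim != 1:
            raise ValueError("concentrations and tensions must be 1-D, equal length")
        if (c <= 0).any():
            raise ValueError("concentrations must be positive")
        if not (np.diff(c) > 0).all():
            raise ValueError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class ActivityResult:
    sample_id: str
    active: bool
    p: float
    t: float
    sample_mean: float
    control_mean: float


@dataclass(frozen=True)
class CMCEstimate:
    """Breakpoint fit of a tension curve.

    ``cmc`` is None when no breakpoint was detected (flat or near-flat
    curve); ``slope`` is the pre-break slope in mN/m per log10(mg/mL).
    """

    cmc: float | None
    plateau_tension: float
    slope: float
    sse: float
    detected: bool


def flag_active(
    sample: TensionMeasurement | Sequence[float],
    control: TensionMeasurement | Sequence[float],
    alpha: float = 0.05,
) -> ActivityResult:
    """Two-sided equal-variance t test with a reduction-only decision.

    Active iff p <= alpha AND the sample mean is below the control mean:
    surfactant activity means the tension went *down*, so a significant rise
    is still "not active".
    """
    if not isinstance(sample, TensionMeasurement):
        sample = TensionMeasurement("sample", tuple(float(v) for v in sample))
    if not isinstance(control, TensionMeasurement):
        control = TensionMeasurement("control", tuple(float(v) for v in control))
    if len(sample.replicates) < 2 or len(control.replicates) < 2:
        raise ValueError("need >= 2 replicates per group for a variance estimate")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    t, p = stats.ttest_ind(sample.replicates, control.replicates, equal_var=True)
    if np.isnan(p):  # both groups constant and equal
        t, p = 0.0, 1.0
    active = (p <= alpha) and (sample.mean < control.mean)
    return ActivityResult(
        sample_id=sample.sample_id,
        active=bool(active),
        p=float(p),
        t=float(t),
        sample_mean=sample.mean,
        control_mean=control.mean,
    )


class CMCEstimator(BaseEstimator):
    """Segmented (broken-stick) fit of surface tension vs log10 concentration.

    Model: ``tension(x) = plateau + slope * min(x - x_b, 0)`` with
    ``x = log10(concentration)``, ``slope <= 0`` and breakpoint ``x_b``; the
    CMC is ``10 ** x_b``.  For a fixed breakpoint the model is linear in
    (plateau, slope) and solved in closed form; the breakpoint itself is
    chosen by exhaustive least squares over ``n_candidates`` points spaced
    between the 2nd and (n-1)th observed log concentrations — deterministic,
    with no initialization sensitivity.

    Parameters
    ----------
    n_candidates : int
        Size of the breakpoint search grid (resolution of the estimate).
    min_slope : float
        Detection threshold: a fitted pre-break slope shallower than this
        (in mN/m per decade; remember slopes are negative) means the curve
        is effectively flat and no CMC is reported.

    Attributes (after fit)
    ----------------------
    cmc_ : float or None
    plateau_ : float
    slope_ : float
    sse_ : float
    detected_ : bool
    """

    def __init__(self, n_candidates: int = 200, min_slope: float = -1.0):
        self.n_candidates = n_candidates
        self.min_slope = min_slope

    def fit(self, concentrations, tensions=None) -> "CMCEstimator":
        if isinstance(concentrations, TensionCurve):
            curve = concentrations
        else:
            curve = TensionCurve(
                tuple(float(c) for c in concentrations),
                tuple(float(t) for t in tensions),
            )
        c = np.asarray(curve.concentrations, dtype=float)
        t = np.asarray(curve.tensions, dtype=float)
        n = c.size
        if n < 5:
            raise ValueError(f"CMC fitting needs >= 5 points, got {n}")
        if np.allclose(t, t[0]):
            self._set_flat(t)
            return self
        x = np.log10(c)

        # candidate breakpoints strictly between the 2nd and (n-1)th points
        grid = np.linspace(x[1], x[-2], int(self.n_candidates))
        # closed-form 2-parameter LS for every candidate, vectorized:
        # z_ij = min(x_j - grid_i, 0); t ~ plateau + slope * z
        Z = np.minimum(x[None, :] - grid[:, None], 0.0)
        zbar = Z.mean(axis=1)
        tbar = t.mean()
        cov = ((Z - zbar[:, None]) * (t - tbar)[None, :]).mean(axis=1)
        var = ((Z - zbar[:, None]) ** 2).mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
        slope = np.minimum(slope, 0.0)  # plateau may not sit above the pre-break leg
        plateau = tbar - slope * zbar
        resid = t[None, :] - (plateau[:, None] + slope[:, None] * Z)
        sse = (resid**2).sum(axis=1)
        best = int(np.argmin(sse))

        self.slope_ = float(slope[best])
        self.plateau_ = float(plateau[best])
        self.sse_ = float(sse[best])
        if self.slope_ > self.min_slope:  # too shallow: effectively flat
            self.cmc_ = None
            self.detected_ = False
            return self
        self.cmc_ = float(10.0 ** grid[best])
        self.detected_ = True

        # warn on a non-monotone pre-break rise (tension should fall toward CMC)
        pre = t[x < grid[best]]
        if pre.size >= 2 and np.any(np.diff(pre) > 1.0):
            warnings.warn(
                "tension rises before the breakpoint; the pre-CMC leg is "
                "non-monotone and the fit may be unreliable",
                stacklevel=2,
            )
        return self

    def _set_flat(self, t: np.ndarray) -> None:
        self.cmc_ = None
        self.plateau_ = float(np.mean(t))
        self.slope_ = 0.0
        self.sse_ = float(np.sum((t - np.mean(t)) ** 2))
        self.detected_ = False

    def estimate_(self) -> CMCEstimate:
        check_is_fitted(self, "plateau_")
        return CMCEstimate(
            cmc=self.cmc_,
            plateau_tension=self.plateau_,
            slope=self.slope_,
            sse=self.sse_,
            detected=self.detected_,
        )


def estimate_cmc(
    curve: TensionCurve, n_candidates: int = 200, min_slope: float = -1.0
) -> CMCEstimate:
    """Estimate the CMC from a tension curve; wrapper over :class:`CMCEstimator`."""
    est = CMCEstimator(n_candidates=n_candidates, min_slope=min_slope)
    return est.fit(curve).estimate_()
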