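"""Plackett-Burman screening and steepest-ascent path construction.

A 12-run Plackett-Burman design estimates up to 11 main effects from 12
two-level runs.  Effects are the +1/-1 response-mean contrasts; because the
columns are orthogonal and balanced, every effect shares the same standard
error, ``se = 2 * sqrt(MSE / n)``, and significance is judged by a two-sided
t test on the residual degrees of freedom of the main-effects model.  The
significant factors then seed a steepest-ascent experiment: an arithmetic
progression of natural-unit trial conditions walked until the response turns
over; the best trial becomes the center of the follow-up response-surface
design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .design import DesignMatrix, FactorDef

__all__ = [
    "PB12_GENERATOR_ROW",
    "PlackettBurmanScreen",
    "PBResult",
    "AscentPath",
    "generate_pb12",
    "fit_pb",
    "significant_factors",
    "build_ascent_path",
    "select_center",
]

# Standard cyclic generator for the 12-run Plackett-Burman design: the 11
# cyclic shifts of this row plus an all-minus run give a balanced, mutually
# orthogonal two-level matrix in 11 columns.
PB12_GENERATOR_ROW = (1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1)


def pb12_full_matrix() -> np.ndarray:
    """The full 12x11 Plackett-Burman coded matrix (cyclic construction)."""
    gen = np.array(PB12_GENERATOR_ROW, dtype=float)
    rows = [np.roll(gen, shift) for shift in range(11)]
    rows.append(-np.ones(11))
    return np.vstack(rows)


def generate_pb12(factors: Sequence[FactorDef]) -> DesignMatrix:
    """12-run Plackett-Burman design carrying the given factors.

    The first k columns of the full 11-column cyclic matrix are assigned to
    the factors in order; remaining columns are unused (they could serve as
    dummy-effect columns but this screen derives its error from the residual
    of the main-effects fit instead).
    """
    k = len(factors)
    if not 1 <= k <= 11:
        raise ValueError(f"a 12-run PB design supports 1..11 factors, got {k}")
    full = pb12_full_matrix()
    return DesignMatrix(factors=tuple(factors), coded=full[:, :k], kind="PB")


@dataclass(frozen=True)
class PBResult:
    """Per-factor screening statistics from a Plackett-Burman fit."""

    factors: tuple[str, ...]
    effects: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    residual_df: int
    intercept: float
    mse: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": self.factors,
                "effect": self.effects,
                "se": self.se,
                "t": self.t,
                "p": self.p,
            }
        )


class PlackettBurmanScreen(BaseEstimator):
    """Main-effects screen for two-level orthogonal designs.

    Fits ``y = b0 + sum_i b_i x_i`` by least squares on the coded +/-1
    matrix.  The factor *effect* (high-mean minus low-mean) is ``2 * b_i``;
    orthogonality makes every effect's standard error identical.

    Parameters
    ----------
    alpha : float
        Significance level used by :meth:`significant_factors`.

    Attributes (after fit)
    ----------------------
    effects_, se_, t_, p_ : ndarray per factor
    intercept_ : float
    residual_df_ : int
    mse_ : float
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y) -> "PlackettBurmanScreen":
        if isinstance(X, DesignMatrix):
            self.factor_names_ = list(X.factor_names)
            X = X.coded
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be a 2-D coded design matrix")
        n, k = X.shape
        if y.shape[0] != n:
            raise ValueError(f"responses ({y.shape[0]}) must match runs ({n})")
        if not np.isin(X, (-1.0, 1.0)).all():
            raise ValueError("screening design must be two-level (+/-1 coded)")
        # balance and orthogonality also catch corrupted run sheets
        # (a duplicated or missing run unbalances some column)
        if not np.allclose(X.sum(axis=0), 0):
            raise ValueError("design columns are not balanced")
        gram = X.T @ X
        if not np.allclose(gram, n * np.eye(k)):
            raise ValueError("design columns are not mutually orthogonal")
        if not np.isfinite(y).all():
            raise ValueError("responses contain missing or non-finite values")
        residual_df = n - (k + 1)
        if residual_df <= 0:
            raise ValueError(
                f"no residual degrees of freedom: {n} runs, {k} factors"
            )
        if not hasattr(self, "factor_names_") or len(self.factor_names_) != k:
            self.factor_names_ = [f"x{i + 1}" for i in range(k)]

        design = np.column_stack([np.ones(n), X])
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        sse = float(resid @ resid)
        # an exact fit (e.g. noiseless synthetic responses) has no error term:
        # report zero effects-scale uncertainty and p = 1 rather than 0/0 noise
        exact = sse <= 1e-20 * max(1.0, float(y @ y))
        mse = 0.0 if exact else sse / residual_df
        effects = 2.0 * beta[1:]
        se = np.full(k, 2.0 * np.sqrt(mse / n))
        if exact:
            t = np.zeros(k)
            p = np.ones(k)
        else:
            t = effects / se
            p = 2.0 * stats.t.sf(np.abs(t), residual_df)

        self.n_features_in_ = k
        self.intercept_ = float(beta[0])
        self.effects_ = effects
        self.se_ = se
        self.t_ = t
        self.p_ = p
        self.mse_ = mse
        self.residual_df_ = residual_df
        return self

    def result_(self) -> PBResult:
        check_is_fitted(self, "effects_")
        return PBResult(
            factors=tuple(self.factor_names_),
            effects=self.effects_,
            se=self.se_,
            t=self.t_,
            p=self.p_,
            residual_df=self.residual_df_,
            intercept=self.intercept_,
            mse=self.mse_,
        )

    def significant_factors(self, alpha: float | None = None) -> list[tuple[str, int]]:
        check_is_fitted(self, "effects_")
        return significant_factors(self.result_(), alpha if alpha is not None else self.alpha)


def fit_pb(design: DesignMatrix | np.ndarray, responses: Sequence[float]) -> PBResult:
    """Fit the main-effects screening model; thin wrapper over the estimator."""
    if isinstance(design, DesignMatrix) and design.kind != "PB":
        raise ValueError(f"expected a PB design, got kind={design.kind!r}")
    return PlackettBurmanScreen().fit(design, responses).result_()


def significant_factors(result: PBResult, alpha: float = 0.05) -> list[tuple[str, int]]:
    """Factors with p <= alpha, annotated with the sign of their effect."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    out = []
    for name, eff, p in zip(result.factors, result.effects, result.p):
        if p <= alpha:
            out.append((name, 1 if eff >= 0 else -1))
    return out


@dataclass(frozen=True)
class AscentPath:
    """Arithmetic progression of natural-unit trial conditions."""

    factor_names: tuple[str, ...]
    start: np.ndarray
    increments: np.ndarray
    n_trials: int
    yields: np.ndarray | None = None

    @property
    def trials(self) -> np.ndarray:
        j = np.arange(self.n_trials)[:, None]
        return self.start[None, :] + j * self.increments[None, :]

    def with_yields(self, yields: Sequence[float]) -> "AscentPath":
        y = np.asarray(yields, dtype=float)
        if y.shape != (self.n_trials,):
            raise ValueError(f"need {self.n_trials} yields, got {y.shape}")
        return AscentPath(
            factor_names=self.factor_names,
            start=self.start,
            increments=self.increments,
            n_trials=self.n_trials,
            yields=y,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.trials, columns=list(self.factor_names))
        df.insert(0, "trial", np.arange(1, self.n_trials + 1))
        if self.yields is not None:
            df["yield"] = self.yields
        return df


def build_ascent_path(
    start: Sequence[float],
    end: Sequence[float],
    n_trials: int,
    factor_names: Sequence[str] | None = None,
) -> AscentPath:
    """Uniform steepest-ascent path from ``start`` to ``end`` (inclusive).

    Trial j (1-based) sits at start + (j-1) * (end - start)/(n_trials - 1).
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if start.shape != end.shape or start.ndim != 1:
        raise ValueError("start and end must be 1-D and the same length")
    if n_trials < 2:
        raise ValueError("an ascent path needs at least 2 trials")
    if np.allclose(start, end):
        raise ValueError("start equals end in every factor: no direction to ascend")
    if factor_names is None:
        factor_names = tuple(f"x{i + 1}" for i in range(start.size))
    increments = (end - start) / (n_trials - 1)
    return AscentPath(
        factor_names=tuple(factor_names),
        start=start,
        increments=increments,
        n_trials=int(n_trials),
    )


def select_center(path: AscentPath) -> tuple[int, np.ndarray]:
    """Pick the best ascent trial as the response-surface center point.

    Returns the 1-based index of the maximum-yield trial (earliest on ties)
    and its natural levels.  Warns when the maximum sits on the last trial
    (the optimum may lie beyond the path) or when all yields tie.
    """
    if path.yields is None:
        raise ValueError("ascent path has no yields; attach them with with_yields()")
    y = path.yields
    idx = int(np.argmax(y))  # first maximal index
    if np.allclose(y, y[0]):
        warnings.warn(
            "all ascent yields are equal; defaulting to trial 1", stacklevel=2
        )
    elif idx == path.n_trials - 1:
        warnings.warn(
            "maximum yield at the last ascent trial: the optimum may lie "
            "beyond the explored path",
            stacklevel=2,
        )
    return idx + 1, path.trials[idx]
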