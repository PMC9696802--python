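"""Box-Behnken response-surface fitting and box-constrained optimization.

The three-factor Box-Behnken design places runs at the midpoints of the
edges of the coded cube: the 12 points {(+/-1, +/-1, 0), (+/-1, 0, +/-1),
(0, +/-1, +/-1)}, optionally augmented with center replicates.  Without
center points the design has a structural alias: every run satisfies
x1^2 + x2^2 + x3^2 = 2, so the three quadratic columns and the intercept are
linearly dependent and one quadratic term cannot be estimated (it is reported
with zero degrees of freedom).

The response is modelled as a full second-order polynomial in the coded
variables, fitted by ordinary least squares.  Term significance uses partial
(extra) sums of squares against the full model, and the fitted surface is
maximized exactly over the coded cube by enumerating the faces of the box and
solving each face's restricted stationary-point system in closed form.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .design import DesignMatrix, FactorDef

__all__ = [
    "QuadraticModel",
    "AnovaTable",
    "OptimumResult",
    "QuadraticResponseSurface",
    "generate_bbd",
    "detect_aliasing",
    "fit_quadratic",
    "anova_partial",
    "predict",
    "optimize_box",
]


# ---------------------------------------------------------------------------
# term bookkeeping

def linear_term(name: str) -> str:
    return name

def interaction_term(a: str, b: str) -> str:
    return f"{a}:{b}"

def quadratic_term(name: str) -> str:
    return f"{name}^2"


def full_quadratic_terms(names: Sequence[str]) -> list[str]:
    """Canonical term order: linear, pairwise interactions, quadratics."""
    terms = [linear_term(n) for n in names]
    terms += [interaction_term(a, b) for a, b in itertools.combinations(names, 2)]
    terms += [quadratic_term(n) for n in names]
    return terms


def _term_column(term: str, names: Sequence[str], X: np.ndarray) -> np.ndarray:
    idx = {n: j for j, n in enumerate(names)}
    if term.endswith("^2"):
        return X[:, idx[term[:-2]]] ** 2
    if ":" in term:
        a, b = term.split(":")
        return X[:, idx[a]] * X[:, idx[b]]
    return X[:, idx[term]]


def build_model_matrix(
    X: np.ndarray, names: Sequence[str], terms: Sequence[str]
) -> np.ndarray:
    cols = [np.ones(X.shape[0])]
    cols += [_term_column(t, names, X) for t in terms]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# model container

@dataclass(frozen=True)
class QuadraticModel:
    """Second-order polynomial on coded variables.

    ``Y = intercept + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2``

    Terms absent from the dictionaries (e.g. an aliased quadratic) contribute
    exactly zero.  ``coding`` maps factor name -> (center, step) for decoding
    coded points back to natural units.
    """

    factor_names: tuple[str, ...]
    intercept: float
    linear: dict[str, float] = field(default_factory=dict)
    interaction: dict[str, float] = field(default_factory=dict)  # keys "A:B"
    quadratic: dict[str, float] = field(default_factory=dict)  # keys by factor name
    coding: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        names = set(self.factor_names)
        for key in self.linear:
            if key not in names:
                raise ValueError(f"unknown linear term {key!r}")
        for key in self.quadratic:
            if key not in names:
                raise ValueError(f"unknown quadratic term {key!r}")
        for key in self.interaction:
            a, _, b = key.partition(":")
            if a not in names or b not in names:
                raise ValueError(f"unknown interaction term {key!r}")

    @property
    def k(self) -> int:
        return len(self.factor_names)

    def quadratic_form(self) -> tuple[float, np.ndarray, np.ndarray]:
        """Return (c, b, Q) with Y(x) = c + b.x + x.Q.x, Q symmetric."""
        idx = {n: j for j, n in enumerate(self.factor_names)}
        b = np.zeros(self.k)
        Q = np.zeros((self.k, self.k))
        for name, coef in self.linear.items():
            b[idx[name]] = coef
        for name, coef in self.quadratic.items():
            Q[idx[name], idx[name]] = coef
        for key, coef in self.interaction.items():
            a, _, c2 = key.partition(":")
            i, j = idx[a], idx[c2]
            Q[i, j] += coef / 2.0
            Q[j, i] += coef / 2.0
        return self.intercept, b, Q

    def predict(self, coded: Sequence[float] | np.ndarray) -> float | np.ndarray:
        x = np.asarray(coded, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != self.k:
            raise ValueError(f"expected {self.k}-dimensional points, got {x.shape[1]}")
        c, b, Q = self.quadratic_form()
        y = c + x @ b + np.einsum("ni,ij,nj->n", x, Q, x)
        return float(y[0]) if single else y

    def decode(self, coded: Sequence[float]) -> np.ndarray:
        if self.coding is None:
            raise ValueError("model carries no coding (center, step per factor)")
        coded = np.asarray(coded, dtype=float)
        centers = np.array([self.coding[n][0] for n in self.factor_names])
        steps = np.array([self.coding[n][1] for n in self.factor_names])
        return centers + coded * steps

    def encode(self, natural: Sequence[float]) -> np.ndarray:
        if self.coding is None:
            raise ValueError("model carries no coding (center, step per factor)")
        natural = np.asarray(natural, dtype=float)
        centers = np.array([self.coding[n][0] for n in self.factor_names])
        steps = np.array([self.coding[n][1] for n in self.factor_names])
        return (natural - centers) / steps

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        coef = {"(Intercept)": self.intercept}
        coef.update(self.linear)
        coef.update({k: v for k, v in self.interaction.items()})
        coef.update({quadratic_term(k): v for k, v in self.quadratic.items()})
        return {
            "factors": list(self.factor_names),
            "coefficients": coef,
            "coding": {k: list(v) for k, v in self.coding.items()}
            if self.coding
            else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, data: Mapping) -> "QuadraticModel":
        names = tuple(data["factors"])
        linear, interaction, quadratic = {}, {}, {}
        intercept = 0.0
        for key, value in data["coefficients"].items():
            if key == "(Intercept)":
                intercept = float(value)
            elif key.endswith("^2"):
                quadratic[key[:-2]] = float(value)
            elif ":" in key:
                interaction[key] = float(value)
            else:
                linear[key] = float(value)
        coding = data.get("coding")
        if coding is not None:
            coding = {k: (float(v[0]), float(v[1])) for k, v in coding.items()}
        return cls(
            factor_names=names,
            intercept=intercept,
            linear=linear,
            interaction=interaction,
            quadratic=quadratic,
            coding=coding,
        )

    @classmethod
    def from_json(cls, path) -> "QuadraticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# design generation and aliasing

_BBD3_EDGES = [
    (-1, -1, 0), (1, -1, 0), (-1, 1, 0), (1, 1, 0),
    (-1, 0, -1), (1, 0, -1), (-1, 0, 1), (1, 0, 1),
    (0, -1, -1), (0, 1, -1), (0, -1, 1), (0, 1, 1),
]


def generate_bbd(factors: Sequence[FactorDef], n_center: int = 0) -> DesignMatrix:
    """Three-factor Box-Behnken design: 12 edge midpoints + center replicates.

    With ``n_center = 0`` the run count is 12 (corrected-total df 11) and the
    three quadratic columns are collinear with the intercept
    (x1^2 + x2^2 + x3^2 = 2 in every run), so one quadratic is inestimable.
    """
    if len(factors) != 3:
        raise ValueError(
            f"only the 3-factor Box-Behnken design is supported, got {len(factors)}"
        )
    if n_center < 0:
        raise ValueError("n_center must be >= 0")
    rows = np.array(_BBD3_EDGES, dtype=float)
    if n_center:
        rows = np.vstack([rows, np.zeros((n_center, 3))])
    return DesignMatrix(factors=tuple(factors), coded=rows, kind="BBD")


def detect_aliasing(
    design: DesignMatrix | np.ndarray,
    terms: Sequence[str] | None = None,
    names: Sequence[str] | None = None,
    drop: str | Sequence[str] = "last",
) -> tuple[list[str], list[str]]:
    """Split candidate terms into (estimable, dropped-with-zero-df).

    Rank analysis of the model matrix.  When the quadratic columns plus the
    intercept are linearly dependent (the centerless Box-Behnken identity),
    quadratic terms are dropped until the matrix has full column rank.

    ``drop`` selects the sacrifice: "last" drops quadratics starting from the
    last declared factor (the default, deterministic rule), or pass explicit
    term names (e.g. ``["E^2"]``) to choose.
    """
    if isinstance(design, DesignMatrix):
        X, names = design.coded, list(design.factor_names)
    else:
        X = np.asarray(design, dtype=float)
        names = list(names) if names is not None else [f"x{i+1}" for i in range(X.shape[1])]
    if terms is None:
        terms = full_quadratic_terms(names)
    terms = list(terms)
    if "(Intercept)" in terms:
        raise ValueError("the intercept is implicit and never droppable")

    if isinstance(drop, str):
        if drop != "last":
            raise ValueError("drop must be 'last' or a list of term names")
        priority = [quadratic_term(n) for n in reversed(names)]
    else:
        priority = list(drop)
        for t in priority:
            if not t.endswith("^2"):
                raise ValueError(f"only quadratic terms may be dropped, got {t!r}")

    def rank_of(term_list: list[str]) -> int:
        M = build_model_matrix(X, names, term_list)
        return int(np.linalg.matrix_rank(M))

    kept = terms
    dropped: list[str] = []
    while rank_of(kept) < len(kept) + 1:
        candidates = [t for t in priority if t in kept]
        if not candidates:
            raise ValueError(
                "model matrix is rank deficient and no droppable quadratic remains"
            )
        victim = candidates[0]
        kept = [t for t in kept if t != victim]
        dropped.append(victim)
    return kept, dropped


# ---------------------------------------------------------------------------
# fitting

class QuadraticResponseSurface(BaseEstimator, RegressorMixin):
    """Second-order response-surface model on coded variables (OLS).

    Parameters
    ----------
    terms : "full" or list of term strings
        Candidate model terms; "full" means all linear, pairwise interaction
        and quadratic terms of the design's factors.
    alias_drop : "last" or list of quadratic term names
        Which quadratic to sacrifice when the design cannot estimate them all
        (centerless Box-Behnken).

    Attributes (after fit)
    ----------------------
    model_ : QuadraticModel
    dropped_terms_ : list of aliased terms reported with zero df
    residual_df_, sse_, r2_ : fit summaries
    """

    def __init__(self, terms: str | Sequence[str] = "full", alias_drop="last"):
        self.terms = terms
        self.alias_drop = alias_drop

    def fit(self, X, y) -> "QuadraticResponseSurface":
        coding = None
        if isinstance(X, DesignMatrix):
            names = list(X.factor_names)
            coding = {f.name: (f.center, f.step) for f in X.factors}
            X = X.coded
        else:
            X = np.asarray(X, dtype=float)
            names = [f"x{i + 1}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (runs x factors)")
        n = X.shape[0]
        if y.shape[0] != n:
            raise ValueError(f"responses ({y.shape[0]}) must match runs ({n})")
        if not np.isfinite(y).all():
            raise ValueError("responses contain non-finite values")

        candidates = (
            full_quadratic_terms(names) if self.terms == "full" else list(self.terms)
        )
        kept, dropped = detect_aliasing(X, candidates, names=names, drop=self.alias_drop)
        M = build_model_matrix(X, names, kept)
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError("model matrix rank deficient after aliasing removal")
        beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
        fitted = M @ beta
        resid = y - fitted
        sse = float(resid @ resid)
        ss_total = float(np.sum((y - y.mean()) ** 2))

        linear, interaction, quadratic = {}, {}, {}
        for term, coef in zip(kept, beta[1:]):
            if term.endswith("^2"):
                quadratic[term[:-2]] = float(coef)
            elif ":" in term:
                interaction[term] = float(coef)
            else:
                linear[term] = float(coef)

        self.factor_names_ = names
        self.terms_ = kept
        self.dropped_terms_ = dropped
        self.model_ = QuadraticModel(
            factor_names=tuple(names),
            intercept=float(beta[0]),
            linear=linear,
            interaction=interaction,
            quadratic=quadratic,
            coding=coding,
        )
        self.n_features_in_ = X.shape[1]
        self.residual_df_ = n - M.shape[1]
        self.sse_ = sse
        self.ss_total_ = ss_total
        self.r2_ = 1.0 - sse / ss_total if ss_total > 0 else float("nan")
        self._X_fit = X
        self._y_fit = y
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        if isinstance(X, DesignMatrix):
            X = X.coded
        return np.atleast_1d(self.model_.predict(np.asarray(X, dtype=float)))

    def anova(self) -> "AnovaTable":
        check_is_fitted(self, "model_")
        return anova_partial(
            self._X_fit, self._y_fit, terms=self.terms_,
            dropped=self.dropped_terms_, names=self.factor_names_,
        )


def fit_quadratic(
    design: DesignMatrix | np.ndarray,
    responses: Sequence[float],
    terms: str | Sequence[str] = "full",
    alias_drop="last",
) -> QuadraticModel:
    """OLS second-order fit on coded variables; wrapper over the estimator."""
    est = QuadraticResponseSurface(terms=terms, alias_drop=alias_drop)
    return est.fit(design, responses).model_


# ---------------------------------------------------------------------------
# ANOVA

@dataclass(frozen=True)
class AnovaTable:
    """Partial (extra) sum-of-squares ANOVA for a fitted response surface."""

    rows: pd.DataFrame  # columns: source, ss, df, ms, F, p

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def __getitem__(self, source: str) -> pd.Series:
        match = self.rows[self.rows["source"] == source]
        if match.empty:
            raise KeyError(source)
        return match.iloc[0]


def anova_partial(
    design: DesignMatrix | np.ndarray,
    responses: Sequence[float],
    terms: Sequence[str] | None = None,
    dropped: Sequence[str] | None = None,
    names: Sequence[str] | None = None,
) -> AnovaTable:
    """Per-term partial-SS ANOVA against the full fitted model.

    Each term's SS is the increase in residual SS when that term alone is
    removed from the full model (so, unlike sequential SS, per-term SS need
    not add up to the model SS).  F = MS_term / MS_residual with the residual
    df of the full model; aliased terms get SS 0, df 0 and blank F/p.
    """
    if isinstance(design, DesignMatrix):
        X, names = design.coded, list(design.factor_names)
    else:
        X = np.asarray(design, dtype=float)
        names = list(names) if names is not None else [f"x{i+1}" for i in range(X.shape[1])]
    y = np.asarray(responses, dtype=float).ravel()
    if terms is None:
        terms, auto_dropped = detect_aliasing(X, names=names)
        dropped = list(auto_dropped) if dropped is None else list(dropped)
    else:
        terms = list(terms)
        dropped = list(dropped) if dropped is not None else []

    def sse_for(term_list: Sequence[str]) -> float:
        M = build_model_matrix(X, names, list(term_list))
        beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    n = X.shape[0]
    sse_full = sse_for(terms)
    residual_df = n - (len(terms) + 1)
    if residual_df < 1:
        raise ValueError(
            "no residual degrees of freedom: ANOVA undefined for a saturated fit"
        )
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ms_resid = sse_full / residual_df
    if sse_full <= 1e-10 * max(ss_total, np.finfo(float).tiny):
        raise ValueError(
            "residual sum of squares is zero: the model interpolates the data "
            "and no error term exists for ANOVA"
        )
    ss_model = ss_total - sse_full
    df_model = len(terms)

    records = []
    f_model = (ss_model / df_model) / ms_resid
    records.append(
        ("Model", ss_model, df_model, ss_model / df_model, f_model,
         float(stats.f.sf(f_model, df_model, residual_df)))
    )
    for term in terms:
        ss = sse_for([t for t in terms if t != term]) - sse_full
        ss = max(ss, 0.0)
        f = ss / ms_resid
        records.append(
            (term, ss, 1, ss, f, float(stats.f.sf(f, 1, residual_df)))
        )
    for term in dropped:
        records.append((term, 0.0, 0, float("nan"), float("nan"), float("nan")))
    records.append(
        ("Residual", sse_full, residual_df, ms_resid, float("nan"), float("nan"))
    )
    records.append(("Cor Total", ss_total, n - 1, float("nan"), float("nan"), float("nan")))
    rows = pd.DataFrame(records, columns=["source", "ss", "df", "ms", "F", "p"])
    return AnovaTable(rows=rows)


# ---------------------------------------------------------------------------
# prediction / optimization

def predict(model: QuadraticModel, coded: Sequence[float]) -> float | np.ndarray:
    """Evaluate the polynomial at one or more coded points."""
    return model.predict(coded)


@dataclass(frozen=True)
class OptimumResult:
    """Maximizer of a quadratic surface over the coded box."""

    coded: np.ndarray
    predicted: float
    natural: np.ndarray | None
    at_boundary: tuple[bool, ...]
    factor_names: tuple[str, ...]

    def natural_rounded(self, decimals: int = 1) -> np.ndarray | None:
        """Natural levels rounded for reporting (raw values stay in .natural)."""
        if self.natural is None:
            return None
        return np.round(self.natural, decimals)

    def to_dict(self) -> dict:
        out = {
            "predicted": self.predicted,
            "coded": dict(zip(self.factor_names, self.coded.tolist())),
            "at_boundary": dict(zip(self.factor_names, self.at_boundary)),
        }
        if self.natural is not None:
            out["natural"] = dict(zip(self.factor_names, self.natural.tolist()))
        return out


def optimize_box(
    model: QuadraticModel, bound: float = 1.0, tol: float = 1e-9
) -> OptimumResult:
    """Exact maximization of the quadratic over the cube [-bound, bound]^k.

    Enumerates the face lattice of the box: each face fixes a subset of
    coordinates at +/-bound and leaves the rest free; on each face the
    restricted quadratic's stationary point is solved in closed form and kept
    when it is feasible.  Vertices (the all-fixed faces) guarantee at least
    one candidate, so the search is total and deterministic — no iterative
    ascent, no tolerance tuning.
    """
    if model.k < 1:
        raise ValueError("model must have at least one factor")
    c, b, Q = model.quadratic_form()
    k = model.k
    best_x: np.ndarray | None = None
    best_y = -math.inf
    for assignment in itertools.product((-bound, bound, None), repeat=k):
        free = [i for i, a in enumerate(assignment) if a is None]
        x = np.array([0.0 if a is None else a for a in assignment])
        if free:
            F = np.array(free)
            C = np.array([i for i in range(k) if i not in free], dtype=int)
            # stationary point of the restricted quadratic:
            # 2*Q_FF x_F = -(b_F + 2*Q_FC x_C)
            A = 2.0 * Q[np.ix_(F, F)]
            rhs = -(b[F] + (2.0 * Q[np.ix_(F, C)] @ x[C] if C.size else 0.0))
            sol, _, _, _ = np.linalg.lstsq(A, rhs, rcond=None)
            if not np.allclose(A @ sol, rhs, atol=1e-10):
                continue  # no stationary point on this face; sub-faces cover it
            if np.any(np.abs(sol) > bound + tol):
                continue
            x[F] = np.clip(sol, -bound, bound)
        y = float(model.predict(x))
        if y > best_y + 1e-15:
            best_y = y
            best_x = x
    assert best_x is not None
    at_boundary = tuple(bool(abs(abs(v) - bound) <= 1e-9) for v in best_x)
    natural = model.decode(best_x) if model.coding is not None else None
    return OptimumResult(
        coded=best_x,
        predicted=best_y,
        natural=natural,
        at_boundary=at_boundary,
        factor_names=model.factor_names,
    )
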