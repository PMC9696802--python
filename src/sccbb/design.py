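"""Shared experimental-design containers: factor definitions and coded run tables.

Factors live in natural units (g/L, h, pH units, ...) and are mapped to coded
variables on [-1, 1] by the usual affine transform
``coded = (natural - center) / step`` with ``center = (low + high)/2`` and
``step = (high - low)/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FactorDef", "DesignMatrix", "encode", "decode"]


@dataclass(frozen=True)
class FactorDef:
    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return (self.low + self.high) / 2.0

    @property
    def step(self) -> float:
        return (self.high - self.low) / 2.0


def encode(factors: Sequence[FactorDef], natural: np.ndarray) -> np.ndarray:
    """Natural levels -> coded values on [-1, 1]."""
    natural = np.atleast_2d(np.asarray(natural, dtype=float))
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return (natural - centers) / steps


def decode(factors: Sequence[FactorDef], coded: np.ndarray) -> np.ndarray:
    """Coded values -> natural levels (inverse of :func:`encode`)."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return centers + coded * steps


@dataclass(frozen=True)
class DesignMatrix:
    """A coded run table (entries in {-1, 0, +1}) with its factor metadata."""

    factors: tuple[FactorDef, ...]
    coded: np.ndarray
    kind: str  # "PB" or "BBD"
    coding_note: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        coded = np.asarray(self.coded, dtype=float)
        if coded.ndim != 2 or coded.shape[1] != len(self.factors):
            raise ValueError("coded matrix must be runs x n_factors")
        if not np.isin(coded, (-1.0, 0.0, 1.0)).all():
            raise ValueError("coded entries must be in {-1, 0, +1}")
        if self.kind == "PB":
            if not np.isin(coded, (-1.0, 1.0)).all():
                raise ValueError("PB designs are two-level (+/-1 only)")
            sums = coded.sum(axis=0)
            if not np.allclose(sums, 0):
                raise ValueError("PB columns must be balanced")
            gram = coded.T @ coded
            off = gram - np.diag(np.diag(gram))
            if not np.allclose(off, 0):
                raise ValueError("PB columns must be pairwise orthogonal")
        object.__setattr__(self, "coded", coded)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def natural(self) -> np.ndarray:
        return decode(self.factors, self.coded)

    def to_frame(self, natural: bool = True) -> pd.DataFrame:
        """Run sheet as a DataFrame: run index, coded and (optionally) natural levels."""
        names = self.factor_names
        df = pd.DataFrame(self.coded, columns=[f"{n}_coded" for n in names])
        if natural:
            nat = self.natural()
            for j, n in enumerate(names):
                df[n] = nat[:, j]
        df.insert(0, "run", np.arange(1, self.n_runs + 1))
        return df
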