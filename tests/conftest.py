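"""Shared fixtures: the published screening/ascent/RSM numbers used as oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from sccbb import FactorDef, QuadraticModel

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pb_factors() -> list[FactorDef]:
    """The five screened production factors with their two-level settings."""
    return [
        FactorDef("glucose", 20, 30, "g/L"),
        FactorDef("NaNO3", 1, 3, "g/L"),
        FactorDef("PO4", 20, 25, "g/L"),
        FactorDef("pH", 6.8, 7.2, ""),
        FactorDef("time", 108, 132, "h"),
    ]


@pytest.fixture(scope="session")
def pb_published_rows() -> list[tuple[str, float, float, float]]:
    """Published screen statistics: (factor, effect, t, p)."""
    return [
        ("glucose", 0.1120, 1.19, 0.281),
        ("NaNO3", 1.0537, 11.15, 0.000),
        ("PO4", 0.1637, 1.73, 0.134),
        ("pH", -0.1480, -1.57, 0.168),
        ("time", 0.2520, 2.67, 0.037),
    ]


@pytest.fixture(scope="session")
def ascent_yields() -> np.ndarray:
    """Published yields (g/L) along the 5-trial steepest-ascent path."""
    return np.array([3.55, 6.09, 6.97, 8.23, 6.06])


@pytest.fixture(scope="session")
def bbd_factors() -> list[FactorDef]:
    """RSM factors coded around ascent trial 4 with the ascent increments."""
    return [
        FactorDef("B", 2.0, 3.0, "g/L"),  # NaNO3: center 2.5, step 0.5
        FactorDef("C", 22.5, 25.0, "g/L"),  # PO4^3-: center 23.75, step 1.25
        FactorDef("E", 120, 132, "h"),  # time: center 126, step 6
    ]


@pytest.fixture(scope="session")
def published_surface() -> QuadraticModel:
    """The published fitted quadratic for biosurfactant yield (g/L)."""
    return QuadraticModel(
        factor_names=("B", "C", "E"),
        intercept=8.21,
        linear={"B": -0.4175, "C": -0.125, "E": 0.03},
        interaction={"B:C": 0.0325, "B:E": -0.0075, "C:E": -0.0075},
        quadratic={"B": -1.15, "C": -0.18},
        coding={"B": (2.5, 0.5), "C": (23.75, 1.25), "E": (126.0, 6.0)},
    )


@pytest.fixture(scope="session")
def anova_published_f() -> list[tuple[float, int, int, float]]:
    """Published ANOVA checks: (F, df1, df2, p)."""
    return [
        (114.11, 8, 3, 0.0012),  # model row
        (277.96, 1, 3, 0.0005),  # NaNO3 linear
        (531.84, 1, 3, 0.0002),  # NaNO3 quadratic
        (16.75, 1, 3, 0.0264),
        (12.92, 1, 3, 0.0369),
    ]
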