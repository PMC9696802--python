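"""CSV/YAML readers and writers for the file dialects the CLI consumes.

Plate OD files come in two dialects: a plate-layout matrix (first column the
row letter, header the column numbers) or long format with ``well,od600``
columns.  Run sheets are CSVs with coded factor columns and a ``response``
column; factor definitions are YAML/JSON lists of {name, low, high, units}.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .activity import TensionCurve, TensionMeasurement
from .design import FactorDef
from .plate_screening import IsolateRecord

__all__ = [
    "read_plate_od",
    "read_census",
    "read_isolates",
    "read_factors",
    "read_run_sheet",
    "read_tension_curve",
    "read_tension_samples",
    "write_run_sheet",
]


def read_plate_od(path) -> dict[str, float]:
    """Read an OD file (matrix or long dialect) into a well -> od600 mapping."""
    df = pd.read_csv(path)
    cols = [str(c).strip().lower() for c in df.columns]
    if "well" in cols and "od600" in cols:
        df.columns = cols
        return dict(zip(df["well"].astype(str), df["od600"].astype(float)))
    matrix = pd.read_csv(path, index_col=0)
    from .plate_screening import od_matrix_to_long

    long = od_matrix_to_long(matrix)
    return dict(zip(long["well"], long["od600"]))


def read_census(path) -> tuple[int, int]:
    """Read a `well,status` census CSV; returns (n_blank, n_wells).

    Status values "blank"/"clear"/"0" count as blank; anything else as grown.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "status" not in df.columns:
        raise ValueError("census file needs a 'status' column")
    status = df["status"].astype(str).str.strip().str.lower()
    blank = status.isin({"blank", "clear", "0", "false", "no"})
    return int(blank.sum()), int(len(df))


def read_isolates(path) -> list[IsolateRecord]:
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"isolate_id", "genus", "similarity"}
    if not required.issubset(df.columns):
        raise ValueError(f"isolate table needs columns {sorted(required)}")
    return [
        IsolateRecord(str(r.isolate_id), str(r.genus), float(r.similarity))
        for r in df.itertuples()
    ]


def read_factors(path) -> list[FactorDef]:
    """Read factor definitions from a YAML or JSON list."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, list):
        raise ValueError("factor config must be a list of factor mappings")
    return [
        FactorDef(
            name=str(d["name"]),
            low=float(d["low"]),
            high=float(d["high"]),
            units=str(d.get("units", "")),
        )
        for d in data
    ]


def read_run_sheet(path, factor_names: Sequence[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Read a run sheet CSV; returns (coded design frame, responses)."""
    df = pd.read_csv(path)
    coded_cols = [f"{n}_coded" for n in factor_names]
    missing = [c for c in coded_cols if c not in df.columns]
    if missing:
        raise ValueError(f"run sheet missing coded columns: {missing}")
    if "response" not in df.columns:
        raise ValueError("run sheet needs a 'response' column")
    return df[coded_cols], df["response"].astype(float)


def write_run_sheet(design, path, responses=None) -> None:
    df = design.to_frame()
    if responses is not None:
        df["response"] = list(responses)
    df.to_csv(path, index=False)


def read_tension_curve(path) -> TensionCurve:
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"concentration_mg_ml", "tension_mn_m"}
    if not required.issubset(df.columns):
        raise ValueError(f"curve file needs columns {sorted(required)}")
    df = df.sort_values("concentration_mg_ml")
    return TensionCurve(
        concentrations=tuple(df["concentration_mg_ml"].astype(float)),
        tensions=tuple(df["tension_mn_m"].astype(float)),
    )


def read_tension_samples(path) -> dict[str, TensionMeasurement]:
    """Read replicate tension readings: `sample_id,replicate,tension_mN_m`."""
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"sample_id", "tension_mn_m"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample file needs columns {sorted(required)}")
    out = {}
    for sid, group in df.groupby("sample_id", sort=False):
        out[str(sid)] = TensionMeasurement(
            sample_id=str(sid),
            replicates=tuple(group["tension_mn_m"].astype(float)),
        )
    return out
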