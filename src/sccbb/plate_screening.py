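"""Bookkeeping for plate-based growth / distortion screens and isolate taxonomy.

Growth is called from blank-corrected OD600; surfactant activity arrives as a
manual per-well distortion flag (the optical grid-distortion read is done by
eye at the bench, so only the boolean is ingested).  Isolate collections are
summarized by genus counts (Shannon diversity, Pielou evenness) and by 16S
similarity bins around the species-level identity threshold.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WellRecord",
    "IsolateRecord",
    "CompositionSummary",
    "ScreenSummary",
    "SimilarityBins",
    "call_growth",
    "summarize_screen",
    "evenness",
    "bin_similarity",
]

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")

DEFAULT_GROWTH_THRESHOLD = 0.1  # blank-corrected OD600 turbidity floor
SPECIES_THRESHOLD = 98.65  # 16S % identity conventionally separating species
HIGH_SIMILARITY_THRESHOLD = 99.0


@dataclass(frozen=True)
class WellRecord:
    well_id: str
    od600: float
    growth: bool
    distortion: bool | None = None

    def __post_init__(self) -> None:
        if self.od600 < 0:
            raise ValueError(f"od600 must be >= 0, got {self.od600}")
        if self.distortion and not self.growth:
            raise ValueError(
                f"well {self.well_id}: distortion flagged on a non-growth well "
                "(the distortion screen applies only to turbid wells)"
            )


@dataclass(frozen=True)
class IsolateRecord:
    isolate_id: str
    genus: str
    similarity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity <= 100.0):
            raise ValueError(
                f"similarity must be in [0, 100], got {self.similarity}"
            )


@dataclass(frozen=True)
class ScreenSummary:
    n_wells: int
    n_growth: int
    n_distortion: int

    @property
    def n_blank(self) -> int:
        return self.n_wells - self.n_growth

    @property
    def blank_fraction(self) -> float:
        if self.n_wells == 0:
            return float("nan")
        return self.n_blank / self.n_wells


@dataclass(frozen=True)
class CompositionSummary:
    """Genus counts with Shannon diversity H (nats) and Pielou evenness J."""

    counts: dict[str, int]
    shannon: float
    pielou: float


@dataclass(frozen=True)
class SimilarityBins:
    """Counts of isolates by 16S identity to the nearest published sequence.

    ``high``: similarity > high_threshold (likely known species);
    ``intermediate``: species_threshold <= similarity <= high_threshold;
    ``novel``: similarity < species_threshold (candidate new species).
    """

    high: int
    intermediate: int
    novel: int
    species_threshold: float = SPECIES_THRESHOLD
    high_threshold: float = HIGH_SIMILARITY_THRESHOLD

    @property
    def total(self) -> int:
        return self.high + self.intermediate + self.novel


def _normalize_well_id(row: str, col: int) -> str:
    return f"{row}{col:02d}"


def od_matrix_to_long(od: pd.DataFrame) -> pd.DataFrame:
    """Melt a plate-layout OD matrix (rows A.., columns 1..) to well/od600 rows."""
    df = od.copy()
    df.index = [str(r).strip().upper() for r in df.index]
    try:
        cols = [int(c) for c in df.columns]
    except (TypeError, ValueError) as exc:
        raise ValueError("plate matrix columns must be integer well columns") from exc
    records = []
    for row_label, row in zip(df.index, df.to_numpy(dtype=float)):
        if not re.fullmatch(r"[A-P]", row_label):
            raise ValueError(f"unrecognized plate row label {row_label!r}")
        for col, value in zip(cols, row):
            records.append((_normalize_well_id(row_label, col), value))
    return pd.DataFrame(records, columns=["well", "od600"])


def call_growth(
    od: pd.DataFrame | Mapping[str, float],
    blank_od: float,
    threshold: float = DEFAULT_GROWTH_THRESHOLD,
    distortion: Mapping[str, bool] | None = None,
) -> list[WellRecord]:
    """Call growth per well: growth iff (od600 - blank_od) >= threshold.

    ``od`` is either a plate-layout DataFrame (index = row letters, columns =
    well columns) or a mapping well -> od600.  Optional ``distortion`` flags
    are attached to growth wells only.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if blank_od < 0:
        raise ValueError("blank_od must be >= 0")
    if isinstance(od, pd.DataFrame):
        long = od_matrix_to_long(od)
        items = list(zip(long["well"], long["od600"]))
    else:
        items = [(str(w), float(v)) for w, v in od.items()]
    distortion = distortion or {}
    records = []
    for well, value in items:
        if not math.isfinite(value) or value < 0:
            raise ValueError(f"well {well}: invalid od600 {value!r}")
        growth = (value - blank_od) >= threshold
        records.append(
            WellRecord(
                well_id=well,
                od600=value,
                growth=growth,
                distortion=distortion.get(well) if growth else None,
            )
        )
    return records


def summarize_screen(records: Iterable[WellRecord]) -> ScreenSummary:
    """Totals for a screened plate; blank fraction feeds lambda calibration."""
    records = list(records)
    n_growth = sum(r.growth for r in records)
    n_distortion = sum(bool(r.distortion) for r in records)
    return ScreenSummary(
        n_wells=len(records), n_growth=n_growth, n_distortion=n_distortion
    )


def evenness(counts: Mapping[str, int] | Sequence[int]) -> CompositionSummary:
    """Shannon index (nats) and Pielou evenness of a genus-count composition.

    J = H / ln(S) over the S genera with positive counts; a single-genus
    collection has no evenness to speak of and gets J = 0.
    """
    if isinstance(counts, Mapping):
        named = {str(k): int(v) for k, v in counts.items()}
    else:
        named = {f"genus_{i + 1}": int(v) for i, v in enumerate(counts)}
    if any(v < 0 for v in named.values()):
        raise ValueError("counts must be non-negative")
    positive = {k: v for k, v in named.items() if v > 0}
    if not positive:
        raise ValueError("at least one positive count required")
    values = np.array(list(positive.values()), dtype=float)
    h = float(stats.entropy(values))  # normalizes internally; natural log
    s = len(positive)
    j = 0.0 if s == 1 else h / math.log(s)
    return CompositionSummary(counts=named, shannon=h, pielou=j)


def bin_similarity(
    isolates: Iterable[IsolateRecord] | Sequence[float],
    species_threshold: float = SPECIES_THRESHOLD,
    high_threshold: float = HIGH_SIMILARITY_THRESHOLD,
) -> SimilarityBins:
    """Partition isolates into three 16S similarity bins.

    Intervals are (high, 100], [species, high], [0, species): the species
    threshold itself belongs to the intermediate bin.  Bins are exhaustive
    and disjoint, so the counts always sum to the number of isolates.
    """
    if not species_threshold < high_threshold:
        raise ValueError("species_threshold must be below high_threshold")
    sims = [
        r.similarity if isinstance(r, IsolateRecord) else float(r) for r in isolates
    ]
    for s in sims:
        if not (0.0 <= s <= 100.0):
            raise ValueError(f"similarity must be in [0, 100], got {s}")
    high = sum(s > high_threshold for s in sims)
    novel = sum(s < species_threshold for s in sims)
    intermediate = len(sims) - high - novel
    return SimilarityBins(
        high=high,
        intermediate=intermediate,
        novel=novel,
        species_threshold=species_threshold,
        high_threshold=high_threshold,
    )
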