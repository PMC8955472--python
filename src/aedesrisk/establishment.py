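"""Rule-based establishment labeling from ovitrap slat records.

An ovitrap's removable wooden slat is collected every two weeks during the
surveillance season (ten biweekly periods, ISO calendar weeks 20–39) and
scored positive when *Aedes albopictus* eggs are found on it.  A trap shows
*establishment* in a year when a run of consecutive positive analyzed slats
spans at least 28 days — stable seasonal presence rather than a one-off
introduction.  The 28-day window accommodates surveillance regimes in which
slats are analyzed only at alternate rounds (every 28 days), where two
consecutive positives span exactly 28 days.

"Consecutive" means adjacent in the date-ordered sequence of *analyzed*
slats: unanalyzed slats are invisible to the rule, while an analyzed
negative breaks a run.  A cell-year is established when at least one of the
cell's traps is; a cell-year is *observed* (and hence labeled at all) when
at least one of its traps has at least one analyzed slat that year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, GridError

__all__ = [
    "EstablishmentRun",
    "LabelingError",
    "SPAN_THRESHOLD_DAYS",
    "assign_period",
    "period_weeks",
    "slat_positive",
    "trap_establishment",
    "label_traps",
    "cell_labels",
    "dataset_summary",
    "train_test_split",
    "split_counts",
]

SPAN_THRESHOLD_DAYS = 28
N_PERIODS = 10
FIRST_WEEK = 20  # period 1 = ISO weeks 20-21 ... period 10 = ISO weeks 38-39


class LabelingError(ValueError):
    """Inconsistent slat records (duplicates, out-of-grid traps, bad years)."""


@dataclass(frozen=True)
class EstablishmentRun:
    """A maximal run of consecutive positive analyzed slats for one trap-year."""

    trap_id: str
    year: int
    first_positive_date: pd.Timestamp
    last_positive_date: pd.Timestamp

    @property
    def span_days(self) -> int:
        return (self.last_positive_date - self.first_positive_date).days


def assign_period(date) -> int | None:
    """Biweekly surveillance period (1–10) containing ``date``, else None.

    Period ``p`` covers ISO weeks ``20 + 2(p-1)`` and ``21 + 2(p-1)``;
    dates outside ISO weeks 20–39 fall outside the surveillance season.
    """
    week = pd.Timestamp(date).isocalendar().week
    if FIRST_WEEK <= week <= FIRST_WEEK + 2 * N_PERIODS - 1:
        return (int(week) - FIRST_WEEK) // 2 + 1
    return None


def period_weeks(period: int) -> tuple[int, int]:
    """The two ISO calendar weeks covered by a period."""
    if not 1 <= period <= N_PERIODS:
        raise LabelingError(f"period must be in 1..{N_PERIODS}, got {period}")
    w = FIRST_WEEK + 2 * (period - 1)
    return w, w + 1


def slat_positive(row: pd.Series) -> bool:
    """Positivity: egg_count > 0 when a count is recorded, else the flag."""
    count = row.get("egg_count")
    if count is not None and not pd.isna(count):
        return count > 0
    return bool(row["positive"])


def trap_establishment(
    slats: pd.DataFrame,
    span_threshold_days: int = SPAN_THRESHOLD_DAYS,
    strict: bool = False,
) -> tuple[bool, list[EstablishmentRun]]:
    """Establishment decision for one trap-year from its slat records.

    Parameters
    ----------
    slats
        Records of a single trap and year with columns trap_id, year,
        collection_date, analyzed, positive (egg_count optional).
    span_threshold_days
        A run establishes when its first-to-last positive span reaches
        this many days (``>=`` by default, ``>`` when ``strict``).

    Returns
    -------
    (established, runs) where runs lists every maximal run of consecutive
    positive analyzed slats.
    """
    if slats.empty:
        return False, []
    if slats["trap_id"].nunique() > 1 or slats["year"].nunique() > 1:
        raise LabelingError("trap_establishment expects slats of a single trap-year")
    analyzed = slats[slats["analyzed"].astype(bool)].copy()
    if analyzed.empty:
        return False, []
    dates = pd.to_datetime(analyzed["collection_date"])
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise LabelingError(
            f"duplicate collection date {dup.date()} for trap "
            f"{slats['trap_id'].iloc[0]!r} in {slats['year'].iloc[0]}"
        )
    analyzed = analyzed.assign(_date=dates).sort_values("_date")
    positives = analyzed.apply(slat_positive, axis=1).to_numpy(bool)

    runs: list[EstablishmentRun] = []
    trap_id = str(slats["trap_id"].iloc[0])
    year = int(slats["year"].iloc[0])
    start = None
    date_arr = analyzed["_date"].to_list()
    for i, pos in enumerate(positives):
        if pos and start is None:
            start = i
        if start is not None and (not pos or i == len(positives) - 1):
            end = i - 1 if not pos else i
            runs.append(EstablishmentRun(trap_id, year, date_arr[start], date_arr[end]))
            start = None
    if strict:
        established = any(r.span_days > span_threshold_days for r in runs)
    else:
        established = any(r.span_days >= span_threshold_days for r in runs)
    return established, runs


def label_traps(
    slats: pd.DataFrame,
    span_threshold_days: int = SPAN_THRESHOLD_DAYS,
    strict: bool = False,
) -> pd.DataFrame:
    """Per trap-year establishment decisions over a full slat table.

    Returns a DataFrame (trap_id, year, analyzed_any, established).
    Trap-years with no analyzed slat are reported with
    ``analyzed_any=False`` so the cell-level step can mark them unobserved.
    """
    records = []
    for (trap_id, year), group in slats.groupby(["trap_id", "year"], sort=True):
        analyzed_any = bool(group["analyzed"].astype(bool).any())
        established, _ = trap_establishment(group, span_threshold_days, strict)
        records.append(
            {"trap_id": trap_id, "year": int(year), "analyzed_any": analyzed_any,
             "established": established}
        )
    return pd.DataFrame.from_records(
        records, columns=["trap_id", "year", "analyzed_any", "established"]
    )


def cell_labels(
    trap_results: pd.DataFrame, traps: pd.DataFrame, grid: GridSpec
) -> pd.DataFrame:
    """Aggregate trap-year decisions to cell-year labels.

    Traps are binned to grid cells by half-open intervals.  A cell-year is
    labeled only if observed (some trap in the cell analyzed at least one
    slat that year); the label is the OR over its traps' establishment.

    Returns a DataFrame (cell_row, cell_col, year, established).
    """
    trap_cell: dict[str, tuple[int, int]] = {}
    for _, t in traps.iterrows():
        try:
            trap_cell[t["trap_id"]] = grid.cell_of(float(t["x"]), float(t["y"]))
        except GridError as exc:
            raise GridError(f"trap {t['trap_id']!r} outside the grid: {exc}") from exc
    unknown = set(trap_results["trap_id"]) - set(trap_cell)
    if unknown:
        raise LabelingError(f"trap results reference unknown trap(s): {sorted(unknown)[:5]}")

    observed = trap_results[trap_results["analyzed_any"]]
    if observed.empty:
        return pd.DataFrame(columns=["cell_row", "cell_col", "year", "established"])
    rows = observed.assign(
        cell_row=[trap_cell[t][0] for t in observed["trap_id"]],
        cell_col=[trap_cell[t][1] for t in observed["trap_id"]],
    )
    agg = (
        rows.groupby(["cell_row", "cell_col", "year"], sort=True)["established"]
        .any()
        .reset_index()
    )
    agg["year"] = agg["year"].astype(int)
    return agg


def dataset_summary(labels: pd.DataFrame, trap_results: pd.DataFrame) -> pd.DataFrame:
    """Yearly surveillance bookkeeping.

    One row per year with counts of ovitraps analyzed, ovitraps with
    establishment, cells observed, and cells with establishment.
    """
    years = sorted(set(labels["year"]) | set(trap_results["year"])) if len(labels) or len(trap_results) else []
    records = []
    for year in years:
        tr = trap_results[(trap_results["year"] == year) & trap_results["analyzed_any"]]
        lb = labels[labels["year"] == year]
        records.append(
            {
                "year": int(year),
                "ovitraps_analyzed": int(len(tr)),
                "ovitraps_established": int(tr["established"].sum()),
                "cells_observed": int(len(lb)),
                "cells_established": int(lb["established"].sum()),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["year", "ovitraps_analyzed", "ovitraps_established",
                 "cells_observed", "cells_established"],
    )


def train_test_split(
    labels: pd.DataFrame, train_years: Iterable[int], test_years: Iterable[int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition cell-year labels by year into train and test sets."""
    train_years, test_years = set(train_years), set(test_years)
    overlap = train_years & test_years
    if overlap:
        raise LabelingError(f"train and test years overlap: {sorted(overlap)}")
    train = labels[labels["year"].isin(train_years)].reset_index(drop=True)
    test = labels[labels["year"].isin(test_years)].reset_index(drop=True)
    return train, test


def split_counts(
    summary: pd.DataFrame,
    train_years: Sequence[int],
    test_years: Sequence[int],
    all_years: Sequence[int] | None = None,
) -> dict[str, int]:
    """Bookkeeping totals of a train/test split from a yearly summary table.

    Sums ``cells_observed``/``cells_established`` per split; ``total_records``
    sums over ``all_years`` (default: every year in the summary, including
    years used only to seed the dispersal feature).
    """
    s = summary.set_index("year")
    if all_years is None:
        all_years = list(s.index)
    def _sum(col: str, years: Sequence[int]) -> int:
        return int(s.loc[list(years), col].sum())
    counts = {
        "total_records": _sum("cells_observed", all_years),
        "train_cells": _sum("cells_observed", train_years),
        "train_established": _sum("cells_established", train_years),
        "test_cells": _sum("cells_observed", test_years),
        "test_established": _sum("cells_established", test_years),
    }
    counts["train_non_established"] = counts["train_cells"] - counts["train_established"]
    counts["test_non_established"] = counts["test_cells"] - counts["test_established"]
    return counts
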