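"""Candidate predictor catalog and per-cell-year feature engineering.

The model screens 79 candidate predictors of *Aedes albopictus*
establishment for each grid cell and year:

* terrain morphology (3): ``elevation`` (m a.s.l.), ``aspect`` (degrees),
  ``slope`` (degrees) — static;
* land cover (32): per-cell coverage fractions for the 32 CORINE level-3
  classes present in Switzerland, named ``clc111`` .. ``clc512`` — static;
* resident population (1): ``population`` — static;
* meteorological (42): seasonal summaries (36) plus biweekly extreme-spell
  statistics (6), computed from daily weather of the cell's (coarser)
  meteorological grid cell;
* dispersal (1): ``car distance to establishment``, the minimum travel time
  in minutes from any cell established in the previous year.

Seasons: the *warm season* of year ``y`` is May 1 – Sep 30 of ``y`` (the
reproductive season); the *cold season* is Dec 1 of ``y-1`` – end of
February of ``y`` (the coldest stretch diapausing eggs must survive).
For each season and each daily series Tmin/Tmax/Tmean the summaries are the
mean and the 5th/25th/75th/95th percentiles; for RAIN the 5th and 25th
percentiles are dropped (they are identically zero in practice), leaving
36 seasonal predictors.

Biweekly extreme features aggregate every sliding 14-day window (1-day
step): e.g. *Tmin minimum biweekly average* is the lowest 14-day mean of
daily Tmin anywhere in the calendar year — how cold the coldest prolonged
spell was.  Temperature windows range over the calendar year; RAIN windows
are restricted to lie wholly inside the warm season.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SeasonWindow",
    "FeatureCatalog",
    "NormalizationBounds",
    "FeatureError",
    "CLC_CLASSES",
    "BIWEEKLY_FEATURES",
    "CAR_DISTANCE",
    "season_window",
    "seasonal_statistics",
    "biweekly_extremes",
    "build_feature_catalog",
    "met_features_for_year",
    "build_feature_matrix",
    "fit_normalizer",
    "apply_normalizer",
]


class FeatureError(ValueError):
    """Invalid inputs to feature construction (coverage gaps, bad mappings)."""


# CORINE level-3 land-cover classes distinguished in Switzerland (32).
CLC_CLASSES: tuple[str, ...] = tuple(
    f"clc{code}"
    for code in (
        111, 112, 121, 122, 123, 124, 131, 132, 133, 141, 142,  # artificial
        211, 221, 222, 231, 242, 243,                            # agricultural
        311, 312, 313, 321, 322, 323, 324, 331, 332, 333, 335,   # (semi-)natural
        411, 412,                                                # wetlands
        511, 512,                                                # water bodies
    )
)

TERRAIN_FEATURES = ("elevation", "aspect", "slope")
POPULATION = "population"
CAR_DISTANCE = "car distance to establishment"

_SERIES = ("Tmin", "Tmax", "Tmean", "RAIN")
_STATS = ("avg", "p5", "p25", "p75", "p95")
_RAIN_STATS = ("avg", "p75", "p95")  # p5/p25 of daily rain are ~always 0

BIWEEKLY_FEATURES = (
    "Tmin minimum biweekly maximum",
    "Tmin minimum biweekly average",
    "Tmax maximum biweekly minimum",
    "Tmax maximum biweekly average",
    "warm-s RAIN maximum biweekly average",
    "warm-s RAIN minimum biweekly average",
)

WINDOW_DAYS = 14  # "biweekly": every sliding two-week period, 1-day step


@dataclass(frozen=True)
class SeasonWindow:
    """Inclusive date range of one season of one year."""

    year: int
    season: str  # "warm" | "cold"
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


def season_window(year: int, season: str) -> SeasonWindow:
    """Warm season: May 1 – Sep 30 of ``year``; cold: Dec 1 of ``year-1`` – end of Feb."""
    if season == "warm":
        return SeasonWindow(year, season, pd.Timestamp(year, 5, 1), pd.Timestamp(year, 9, 30))
    if season == "cold":
        feb_end = pd.Timestamp(year, 3, 1) - pd.Timedelta(days=1)
        return SeasonWindow(year, season, pd.Timestamp(year - 1, 12, 1), feb_end)
    raise FeatureError(f"unknown season {season!r}: expected 'warm' or 'cold'")


def _check_coverage(series: pd.Series, dates: pd.DatetimeIndex, what: str) -> pd.Series:
    missing = dates.difference(series.index)
    if len(missing):
        head = ", ".join(str(d.date()) for d in missing[:5])
        raise FeatureError(
            f"{what}: {len(missing)} missing day(s), first gaps: {head}"
        )
    return series.loc[dates]


def seasonal_statistics(series: pd.Series, window: SeasonWindow, series_name: str) -> dict[str, float]:
    """Seasonal mean and percentiles of one daily series over one season.

    Percentiles use linear interpolation between closest order statistics
    (numpy's default, the common "type 7" convention).  For RAIN only avg,
    p75 and p95 are produced.

    Parameters
    ----------
    series
        Daily values indexed by date; must cover every day of ``window``.
    """
    if series_name not in _SERIES:
        raise FeatureError(f"unknown series {series_name!r}")
    values = _check_coverage(series, window.dates(), f"{series_name} {window.season}-s {window.year}").to_numpy(float)
    stats = _RAIN_STATS if series_name == "RAIN" else _STATS
    out: dict[str, float] = {}
    for stat in stats:
        key = f"{window.season}-s {series_name} {stat}"
        if stat == "avg":
            out[key] = float(np.mean(values))
        else:
            out[key] = float(np.percentile(values, int(stat[1:])))
    return out


def _window_aggregates(values: np.ndarray, how: str) -> np.ndarray:
    """Aggregate every full 14-day sliding window of a daily series."""
    if len(values) < WINDOW_DAYS:
        raise FeatureError(f"need at least {WINDOW_DAYS} days, got {len(values)}")
    windows = np.lib.stride_tricks.sliding_window_view(values, WINDOW_DAYS)
    if how == "mean":
        return windows.mean(axis=1)
    if how == "min":
        return windows.min(axis=1)
    if how == "max":
        return windows.max(axis=1)
    raise ValueError(how)


def biweekly_extremes(
    tmin: pd.Series, tmax: pd.Series, rain: pd.Series, year: int
) -> dict[str, float]:
    """Extreme-spell features from sliding 14-day windows.

    Temperature windows slide over the whole calendar year of ``year``
    (full windows only); RAIN windows slide within the warm season.
    """
    year_days = pd.date_range(pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31), freq="D")
    tmin_v = _check_coverage(tmin, year_days, f"Tmin calendar year {year}").to_numpy(float)
    tmax_v = _check_coverage(tmax, year_days, f"Tmax calendar year {year}").to_numpy(float)
    warm = season_window(year, "warm")
    rain_v = _check_coverage(rain, warm.dates(), f"RAIN warm-s {year}").to_numpy(float)
    return {
        "Tmin minimum biweekly maximum": float(_window_aggregates(tmin_v, "max").min()),
        "Tmin minimum biweekly average": float(_window_aggregates(tmin_v, "mean").min()),
        "Tmax maximum biweekly minimum": float(_window_aggregates(tmax_v, "min").max()),
        "Tmax maximum biweekly average": float(_window_aggregates(tmax_v, "mean").max()),
        "warm-s RAIN maximum biweekly average": float(_window_aggregates(rain_v, "mean").max()),
        "warm-s RAIN minimum biweekly average": float(_window_aggregates(rain_v, "mean").min()),
    }


@dataclass(frozen=True)
class FeatureCatalog:
    """Fixed, ordered list of the 79 candidate predictor names."""

    names: tuple[str, ...]
    groups: Mapping[str, tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def validate_names(self, names: Iterable[str]) -> None:
        unknown = [n for n in names if n not in self.names]
        if unknown:
            raise FeatureError(f"unknown feature name(s): {unknown}")


def _seasonal_names() -> tuple[str, ...]:
    names = []
    for season in ("warm", "cold"):
        for series in _SERIES:
            for stat in _RAIN_STATS if series == "RAIN" else _STATS:
                names.append(f"{season}-s {series} {stat}")
    return tuple(names)


def build_feature_catalog() -> FeatureCatalog:
    """The deterministic 79-entry predictor catalog in canonical order."""
    seasonal = _seasonal_names()
    groups = {
        "terrain": TERRAIN_FEATURES,
        "land_cover": CLC_CLASSES,
        "population": (POPULATION,),
        "met_seasonal": seasonal,
        "met_biweekly": BIWEEKLY_FEATURES,
        "travel": (CAR_DISTANCE,),
    }
    names = tuple(n for grp in groups.values() for n in grp)
    assert len(names) == 79
    return FeatureCatalog(names=names, groups=groups)


def met_features_for_year(weather_cell: pd.DataFrame, year: int) -> dict[str, float]:
    """All 42 meteorological predictors for one met-cell and one year.

    ``weather_cell`` holds the daily records of a single met-cell with
    columns date, tmin, tmax, tmean, rain; it must cover Dec 1 of
    ``year-1`` through Dec 31 of ``year``.
    """
    w = weather_cell.set_index(pd.DatetimeIndex(weather_cell["date"])).sort_index()
    tmin, tmax, tmean, rain = (w[c] for c in ("tmin", "tmax", "tmean", "rain"))
    by_name = {"Tmin": tmin, "Tmax": tmax, "Tmean": tmean, "RAIN": rain}
    out: dict[str, float] = {}
    for season in ("warm", "cold"):
        win = season_window(year, season)
        for series_name, series in by_name.items():
            out.update(seasonal_statistics(series, win, series_name))
    out.update(biweekly_extremes(tmin, tmax, rain, year))
    return out


def build_feature_matrix(
    cells: Sequence[tuple[int, int]],
    year: int,
    weather: pd.DataFrame,
    static_layers: pd.DataFrame,
    travel_feature: Mapping[tuple[int, int], float] | np.ndarray,
) -> pd.DataFrame:
    """Assemble the full 79-column predictor matrix for a set of cells.

    Parameters
    ----------
    cells
        (row, col) pairs; one output row per cell, in this order.
    weather
        Daily weather with columns met_cell, date, tmin, tmax, tmean, rain.
    static_layers
        Per-cell static attributes indexed or keyed by (cell_row, cell_col),
        with terrain, clc fractions, population, and a ``met_cell`` column
        mapping each cell to its meteorological grid cell.
    travel_feature
        Car-distance-to-establishment minutes, either a mapping keyed by
        (row, col) or an array aligned with ``cells``.

    Returns
    -------
    DataFrame with one row per cell and the 79 catalog columns in order,
    indexed by (row, col).
    """
    catalog = build_feature_catalog()
    static = static_layers.set_index(["cell_row", "cell_col"]) if "cell_row" in static_layers.columns else static_layers
    missing_cells = [c for c in cells if c not in static.index]
    if missing_cells:
        raise FeatureError(f"cells missing from static layers: {missing_cells[:5]}")
    sub = static.loc[list(cells)]
    if "met_cell" not in sub.columns or sub["met_cell"].isna().any():
        raise FeatureError("every cell must map to exactly one met_cell")

    met_cache: dict[object, dict[str, float]] = {}
    for mc in pd.unique(sub["met_cell"]):
        cell_weather = weather[weather["met_cell"] == mc]
        if cell_weather.empty:
            raise FeatureError(f"no weather records for met_cell {mc!r}")
        met_cache[mc] = met_features_for_year(cell_weather, year)

    if isinstance(travel_feature, Mapping):
        travel = np.array([travel_feature[c] for c in cells], float)
    else:
        travel = np.asarray(travel_feature, float)
        if len(travel) != len(cells):
            raise FeatureError("travel_feature length does not match cells")

    data: dict[str, np.ndarray] = {}
    for name in TERRAIN_FEATURES + CLC_CLASSES + (POPULATION,):
        data[name] = sub[name].to_numpy(float)
    met_rows = [met_cache[mc] for mc in sub["met_cell"]]
    for name in catalog.groups["met_seasonal"] + catalog.groups["met_biweekly"]:
        data[name] = np.array([m[name] for m in met_rows], float)
    data[CAR_DISTANCE] = travel

    out = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(cells, names=["row", "col"]))
    return out[list(catalog.names)]


@dataclass(frozen=True)
class NormalizationBounds:
    """Per-feature min/max observed on a training subset (min–max scaling)."""

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            n: {"min": float(lo), "max": float(hi)}
            for n, lo, hi in zip(self.names, self.mins, self.maxs)
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, float]]) -> "NormalizationBounds":
        names = tuple(d)
        mins = np.array([d[n]["min"] for n in names], float)
        maxs = np.array([d[n]["max"] for n in names], float)
        return cls(names, mins, maxs)


def fit_normalizer(training: pd.DataFrame) -> NormalizationBounds:
    """Record per-feature min/max of the training matrix."""
    if len(training) == 0:
        raise FeatureError("cannot fit normalization bounds on empty data")
    return NormalizationBounds(
        names=tuple(training.columns),
        mins=training.min(axis=0).to_numpy(float),
        maxs=training.max(axis=0).to_numpy(float),
    )


def apply_normalizer(bounds: NormalizationBounds, vectors: pd.DataFrame) -> pd.DataFrame:
    """Rescale to [0, 1] by the stored bounds.

    Features constant in training map to 0; values outside the training
    range are kept (no clipping), so extrapolated data may fall outside
    [0, 1].
    """
    if tuple(vectors.columns) != bounds.names:
        raise FeatureError("column order does not match normalization bounds")
    span = bounds.maxs - bounds.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (vectors.to_numpy(float) - bounds.mins) / safe
    scaled[:, span == 0] = 0.0
    return pd.DataFrame(scaled, index=vectors.index, columns=vectors.columns)
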