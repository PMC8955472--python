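"""Self-contained synthetic surveillance world.

The real inputs (multi-year ovitrap records, gridded daily weather, terrain
and land-cover layers, road travel times) are not publicly redistributable,
so this module generates a synthetic landscape with the statistical
structure the analysis assumes:

* a square 200 m cell grid with a smooth random elevation field (valley
  floor to mountains), slope/aspect derived from it;
* Dirichlet land-cover fractions over the 32 CORINE classes, with urban
  classes concentrated at low elevation, and a log-normal resident
  population scaled by the urban fraction;
* daily weather on a coarser met-grid (1 km emulated as 5x5 model cells):
  seasonal sinusoid minus an elevational lapse plus AR(1) noise for Tmean,
  positive spreads for Tmin/Tmax, zero-inflated gamma rainfall — covering
  Dec 1 of the year before the first modeled year so cold-season features
  are computable;
* a travel-time provider = shortest paths on the 4-connected grid graph
  with per-edge minutes drawn once at world creation;
* a known logistic establishment process: year-1 establishment is seeded,
  later years establish with probability
  ``logistic(intercept + sum(beta * normalized features))`` where the
  car-distance feature is computed against the previous year's established
  set; establishment is absorbing (populations persist once settled);
* ovitrap slats: traps in a fixed subset of cells emit one slat per
  biweekly period, positive with a high rate in truly established
  cell-years and a low background rate otherwise.

Everything is deterministic given the config seed, so downstream stages
(labeling, features, ensemble fitting, mapping) can be tested against a
known ground truth — including recovery of the true coefficient support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import features as ft
from .grid import GridSpec, GridError
from .travel import GridTravelProvider, car_distance_to_establishment

__all__ = [
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "ConfigError",
    "DEFAULT_TRUE_COEFFICIENTS",
    "generate_world",
    "generate_weather",
    "simulate_establishment",
    "write_world",
    "read_world",
]


class ConfigError(ValueError):
    """Invalid synthetic-world configuration."""


# Ground-truth effects on the normalized (min-max per year) feature scale.
# Chosen once as the study conditions: establishment favored at low
# elevation, near last year's populations, in residential areas and in
# urban green areas (breeding-site availability), and disfavored in
# industrial zones (mirroring the residential-vs-industrial colonization
# pattern).  Three constraints drive the choice: each true feature has
# *persistent* spatial variation (the response is cumulative presence, so
# purely transient predictors leave no recoverable footprint); none sits
# inside a tightly correlated feature group (LASSO names one
# representative per group, so truth placed e.g. on one rain statistic
# would be recovered through a near-collinear sibling under an arbitrary
# name); and each has a well-spread distribution after min-max scaling
# (an outlier-compressed feature like slope carries almost no effect per
# unit of its normalized scale).
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "elevation": -4.0,
    ft.CAR_DISTANCE: -6.0,
    "clc112": 3.0,
    "clc121": -3.0,
    "clc142": 3.0,
}


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Study conditions of the synthetic world.

    Defaults give a 40x40 grid (1600 cells), eleven modeled years (one
    seed year for the dispersal feature, eight training years, two held
    out), five true nonzero coefficients, and slat positivity rates of
    0.85 in established vs 0.02 in background cell-years.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    met_grid_factor: int = 5
    # 2004 analog seeds the dispersal feature; 2005-2012 train, 2013-2014 test.
    years: tuple[int, ...] = tuple(range(2004, 2015))
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    intercept: float = -1.5
    seed_cells: tuple[tuple[int, int], ...] | None = None  # None: band-wise lowest cells
    n_seed_cells: int = 5
    n_traps: int = 400
    slat_positive_rate_established: float = 0.85
    slat_positive_rate_background: float = 0.02
    alternate_rounds: bool = False  # analyze only odd periods (post-2013 regime)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("slat_positive_rate_established", "slat_positive_rate_background"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.slat_positive_rate_established <= self.slat_positive_rate_background:
            raise ConfigError("established slat rate must exceed the background rate")
        if self.met_grid_factor < 1:
            raise ConfigError("met_grid_factor must be >= 1")
        if not self.years:
            raise ConfigError("years must be nonempty")
        ft.build_feature_catalog().validate_names(self.true_coefficients)

    def to_jsonable(self) -> dict:
        d = {
            "grid": {k: getattr(self.grid, k) for k in
                     ("origin_x", "origin_y", "cell_size", "n_cols", "n_rows", "crs_label")},
            "met_grid_factor": self.met_grid_factor,
            "years": list(self.years),
            "true_coefficients": dict(self.true_coefficients),
            "intercept": self.intercept,
            "seed_cells": [list(c) for c in self.seed_cells] if self.seed_cells else None,
            "n_seed_cells": self.n_seed_cells,
            "n_traps": self.n_traps,
            "slat_positive_rate_established": self.slat_positive_rate_established,
            "slat_positive_rate_background": self.slat_positive_rate_background,
            "alternate_rounds": self.alternate_rounds,
            "rng_seed": self.rng_seed,
        }
        return d


@dataclass(frozen=True)
class SyntheticWorld:
    """Generated landscape: static layers, met-grid, travel graph, traps."""

    config: SyntheticWorldConfig
    static_layers: pd.DataFrame  # cell_row, cell_col, terrain, clc*, population, met_cell
    met_cells: pd.DataFrame      # met_cell, elevation
    travel: GridTravelProvider
    traps: pd.DataFrame          # trap_id, x, y

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    def cells(self) -> list[tuple[int, int]]:
        return self.grid.all_cells()

    def seed_cells(self) -> tuple[tuple[int, int], ...]:
        """Initial established cells: explicit, or one low-elevation entry
        point per column band (invasion entering at several points along
        the warm edge of the region)."""
        if self.config.seed_cells is not None:
            return self.config.seed_cells
        n = self.config.n_seed_cells
        n_cols = self.grid.n_cols
        edges = np.linspace(0, n_cols, n + 1).astype(int)
        seeds = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            band = self.static_layers[
                (self.static_layers["cell_col"] >= lo) & (self.static_layers["cell_col"] < hi)
            ]
            if band.empty:
                continue
            best = band.nsmallest(1, "elevation").iloc[0]
            seeds.append((int(best["cell_row"]), int(best["cell_col"])))
        return tuple(dict.fromkeys(seeds))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Build the static landscape, met-grid, travel graph and trap network."""
    grid = config.grid
    rows, cols = grid.n_rows, grid.n_cols
    rng = _rng(config.rng_seed, 1)

    # Elevation: north-increasing gradient plus a smoothed random field.
    noise = rng.normal(size=(rows, cols))
    smooth = gaussian_filter(noise, sigma=max(2.0, min(rows, cols) / 8), mode="nearest")
    if smooth.std() > 0:
        smooth = (smooth - smooth.min()) / (smooth.max() - smooth.min())
    gradient = (np.arange(rows, dtype=float)[:, None] / max(rows - 1, 1)) * np.ones((1, cols))
    elevation = 200.0 + 1300.0 * (0.6 * gradient + 0.4 * smooth)

    if rows >= 2 and cols >= 2:
        dz_dy, dz_dx = np.gradient(elevation, grid.cell_size)
    else:  # degenerate grid: flat terrain by convention
        dz_dy = np.zeros_like(elevation)
        dz_dx = np.zeros_like(elevation)
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    aspect = (np.degrees(np.arctan2(dz_dy, dz_dx)) + 360.0) % 360.0

    # Land cover: Dirichlet fractions, urban classes weighted up at low elevation.
    urban_classes = {"clc111", "clc112", "clc121"}
    urban_weight = np.exp(-(elevation - 200.0) / 300.0)  # ~1 on the valley floor
    alphas = np.empty((rows * cols, len(ft.CLC_CLASSES)))
    for j, name in enumerate(ft.CLC_CLASSES):
        base = 0.15
        if name in urban_classes:
            alphas[:, j] = base * (1.0 + 8.0 * urban_weight.ravel())
        else:
            alphas[:, j] = base
    land_cover = np.vstack([rng.dirichlet(a) for a in alphas])

    urban_fraction = land_cover[:, [ft.CLC_CLASSES.index(c) for c in sorted(urban_classes)]].sum(axis=1)
    population = np.round(
        rng.lognormal(mean=np.log(60.0), sigma=0.8, size=rows * cols)
        * (0.05 + urban_fraction)
    ).astype(int)

    met_n_cols = -(-cols // config.met_grid_factor)
    cell_rows, cell_cols = np.divmod(np.arange(rows * cols), cols)
    met_cell = (cell_rows // config.met_grid_factor) * met_n_cols + (
        cell_cols // config.met_grid_factor
    )

    static = pd.DataFrame(
        {
            "cell_row": cell_rows,
            "cell_col": cell_cols,
            "elevation": elevation.ravel(),
            "aspect": aspect.ravel(),
            "slope": slope.ravel(),
            **{name: land_cover[:, j] for j, name in enumerate(ft.CLC_CLASSES)},
            "population": population,
            "met_cell": met_cell,
        }
    )
    met_elev = static.groupby("met_cell")["elevation"].mean().reset_index()
    met_elev.columns = ["met_cell", "elevation"]

    # Travel graph: 4-connected, per-edge minutes drawn once.
    edge_rng = _rng(config.rng_seed, 2)
    a_idx, b_idx = [], []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                a_idx.append(i); b_idx.append(i + 1)
            if r + 1 < rows:
                a_idx.append(i); b_idx.append(i + cols)
    minutes = edge_rng.uniform(0.2, 1.0, size=len(a_idx))
    edges = pd.DataFrame({"cell_a": a_idx, "cell_b": b_idx, "minutes": minutes})
    provider = GridTravelProvider(grid, edges)

    # Fixed trap network: a random subset of cells, one trap per chosen cell.
    trap_rng = _rng(config.rng_seed, 3)
    n_traps = min(config.n_traps, rows * cols)
    trap_cells = trap_rng.choice(rows * cols, size=n_traps, replace=False)
    trap_cells.sort()
    tx, ty = [], []
    for i in trap_cells:
        r, c = divmod(int(i), cols)
        x0, y0 = grid.cell_center(r, c)
        tx.append(x0 + trap_rng.uniform(-0.3, 0.3) * grid.cell_size)
        ty.append(y0 + trap_rng.uniform(-0.3, 0.3) * grid.cell_size)
    traps = pd.DataFrame(
        {"trap_id": [f"T{i:05d}" for i in trap_cells], "x": tx, "y": ty}
    )

    return SyntheticWorld(config=config, static_layers=static, met_cells=met_elev,
                          travel=provider, traps=traps)


def generate_weather(
    world: SyntheticWorld,
    years: Sequence[int] | None = None,
    rng_seed: int | None = None,
    *,
    t_base: float = 11.0,
    t_amp: float = 9.0,
    lapse: float = 0.0065,
    noise_sd: float = 2.0,
    noise_rho: float = 0.7,
    spread_base: float = 1.5,
    rain_wet_prob: float = 0.35,
    rain_gamma_shape: float = 0.8,
    rain_gamma_scale: float = 10.0,
    rain_gradient: float = 0.8,
    start: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Daily weather per met-cell, Dec 1 of ``min(years)-1`` .. Dec 31 of ``max(years)``.

    ``Tmean = t_base + t_amp * cos(2*pi*(doy - 200)/365.25) - lapse*elev + AR(1)``;
    Tmin/Tmax subtract/add positive spreads; RAIN is a zero-inflated gamma
    draw whose scale rises west to east by the relative amplitude
    ``rain_gradient`` — a persistent spatial wetness pattern, as real
    precipitation climatologies have.  The December before the first
    modeled year is always included so that cold-season features of the
    first year are computable.
    """
    years = tuple(years) if years is not None else world.config.years
    if not years:
        raise ConfigError("years must be nonempty")
    seed = world.config.rng_seed if rng_seed is None else rng_seed
    required_start = pd.Timestamp(min(years) - 1, 12, 1)
    if start is None:
        start = required_start
    elif start > required_start:
        raise ConfigError(
            f"weather span must begin no later than {required_start.date()} "
            f"(cold-season prefix of {min(years)}), got {start.date()}"
        )
    dates = pd.date_range(start, pd.Timestamp(max(years), 12, 31), freq="D")
    doy = dates.dayofyear.to_numpy(float)
    seasonal = t_base + t_amp * np.cos(2 * np.pi * (doy - 200.0) / 365.25)

    met_n_cols = -(-world.grid.n_cols // world.config.met_grid_factor)
    frames = []
    for _, mc in world.met_cells.iterrows():
        rng = _rng(seed, 10_000 + int(mc["met_cell"]))
        met_col = int(mc["met_cell"]) % met_n_cols
        frac_x = met_col / max(met_n_cols - 1, 1)
        rain_scale = rain_gamma_scale * (1.0 - rain_gradient / 2.0 + rain_gradient * frac_x)
        n = len(dates)
        if noise_sd > 0:
            eps = rng.normal(0.0, noise_sd * np.sqrt(1 - noise_rho**2), size=n)
            ar = np.empty(n)
            ar[0] = rng.normal(0.0, noise_sd)
            for t in range(1, n):
                ar[t] = noise_rho * ar[t - 1] + eps[t]
        else:
            ar = np.zeros(n)
        tmean = seasonal - lapse * float(mc["elevation"]) + ar
        spread_lo = spread_base + rng.gamma(2.0, 1.0, size=n)
        spread_hi = spread_base + rng.gamma(2.0, 1.0, size=n)
        wet = rng.random(n) < rain_wet_prob
        rain = np.where(wet, rng.gamma(rain_gamma_shape, rain_scale, size=n), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "met_cell": int(mc["met_cell"]),
                    "date": dates,
                    "tmin": tmean - spread_lo,
                    "tmax": tmean + spread_hi,
                    "tmean": tmean,
                    "rain": rain,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _logistic(z: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(z)


def simulate_establishment(
    world: SyntheticWorld, weather: pd.DataFrame, config: SyntheticWorldConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the ground-truth establishment process and emit ovitrap slats.

    Returns
    -------
    truth
        DataFrame (cell_row, cell_col, year, established) for every cell
        and every modeled year.
    slats
        DataFrame (trap_id, year, period, collection_date, analyzed,
        positive, egg_count), one slat per trap per biweekly period.
    """
    config = config or world.config
    catalog = ft.build_feature_catalog()
    catalog.validate_names(config.true_coefficients)
    cells = world.cells()
    years = list(config.years)
    beta = np.array([config.true_coefficients.get(n, 0.0) for n in catalog.names])

    est_rng = _rng(config.rng_seed, 4)
    established: set[tuple[int, int]] = set(world.seed_cells())
    truth_rows = []
    for year_i, year in enumerate(years):
        if year_i > 0:
            dist = car_distance_to_establishment(cells, sorted(established), world.travel)
            X = ft.build_feature_matrix(cells, year, weather, world.static_layers, dist)
            Xn = ft.apply_normalizer(ft.fit_normalizer(X), X)
            p = _logistic(config.intercept + Xn.to_numpy() @ beta)
            new = est_rng.random(len(cells)) < p
            established = established | {
                cell for cell, flag in zip(cells, new) if flag
            }
        for r, c in cells:
            truth_rows.append(
                {"cell_row": r, "cell_col": c, "year": year,
                 "established": (r, c) in established}
            )
    truth = pd.DataFrame.from_records(truth_rows)

    # Ovitrap slats: one per trap per biweekly period.
    slat_rng = _rng(config.rng_seed, 5)
    trap_cell = {
        t["trap_id"]: world.grid.cell_of(t["x"], t["y"]) for _, t in world.traps.iterrows()
    }
    truth_map = {
        (r, c, y): e
        for r, c, y, e in zip(truth["cell_row"], truth["cell_col"], truth["year"], truth["established"])
    }
    slat_rows = []
    for trap_id in world.traps["trap_id"]:
        r, c = trap_cell[trap_id]
        for year in years:
            rate = (
                config.slat_positive_rate_established
                if truth_map[(r, c, year)]
                else config.slat_positive_rate_background
            )
            for period in range(1, 11):
                week = 21 + 2 * (period - 1)  # second ISO week of the period
                date = pd.Timestamp.fromisocalendar(year, week, 5)
                analyzed = True if not config.alternate_rounds else (period % 2 == 1)
                positive = bool(analyzed and slat_rng.random() < rate)
                egg_count = int(1 + slat_rng.poisson(20)) if positive else 0
                slat_rows.append(
                    {"trap_id": trap_id, "year": year, "period": period,
                     "collection_date": date, "analyzed": analyzed,
                     "positive": positive, "egg_count": egg_count}
                )
    slats = pd.DataFrame.from_records(slat_rows)
    return truth, slats


def write_world(
    world: SyntheticWorld,
    weather: pd.DataFrame,
    truth: pd.DataFrame,
    slats: pd.DataFrame,
    outdir: str | Path,
) -> None:
    """Write the full synthetic dataset as CSV files plus a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world.traps.to_csv(out / "traps.csv", index=False)
    slats.to_csv(out / "slats.csv", index=False)
    weather.to_csv(out / "weather.csv", index=False)
    world.static_layers.to_csv(out / "static_layers.csv", index=False)
    world.travel.edges.to_csv(out / "travel_edges.csv", index=False)
    truth.to_csv(out / "truth_labels.csv", index=False)
    manifest = {"config": world.config.to_jsonable(), "seed": world.config.rng_seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def config_from_jsonable(d: Mapping) -> SyntheticWorldConfig:
    grid = GridSpec(**d["grid"]) if "grid" in d else GridSpec()
    kwargs = {k: v for k, v in d.items() if k != "grid"}
    if kwargs.get("years") is not None:
        kwargs["years"] = tuple(kwargs["years"])
    if kwargs.get("seed_cells") is not None:
        kwargs["seed_cells"] = tuple(tuple(c) for c in kwargs["seed_cells"])
    return SyntheticWorldConfig(grid=grid, **kwargs)


def read_world(datadir: str | Path) -> tuple[SyntheticWorld, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load a written synthetic dataset: (world, weather, truth, slats)."""
    d = Path(datadir)
    manifest = json.loads((d / "manifest.json").read_text())
    config = config_from_jsonable(manifest["config"])
    static = pd.read_csv(d / "static_layers.csv")
    edges = pd.read_csv(d / "travel_edges.csv")
    traps = pd.read_csv(d / "traps.csv")
    met = static.groupby("met_cell")["elevation"].mean().reset_index()
    world = SyntheticWorld(
        config=config,
        static_layers=static,
        met_cells=met,
        travel=GridTravelProvider(config.grid, edges),
        traps=traps,
    )
    weather = pd.read_csv(d / "weather.csv", parse_dates=["date"])
    truth = pd.read_csv(d / "truth_labels.csv")
    slats = pd.read_csv(d / "slats.csv", parse_dates=["collection_date"])
    return world, weather, truth, slats
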