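"""Scenario-averaged risk maps and normalized uncertainty maps.

Near-future meteorology is unknown, so recent historical years serve as
weather *scenarios* (the reference analysis used 2015-2018).  Every member
of the ensemble predicts under every scenario, giving members x scenarios
probabilities per cell (8 x 4 = 32 in the reference setting).  From that
stack come:

* yearly mean risk maps (mean over members within one scenario),
* a summary risk map (mean over all member x scenario predictions),
* raw uncertainty maps (population SD of the corresponding prediction
  set), and
* normalized uncertainty maps: every raw SD map is divided by the single
  global maximum SD across all supplied maps, so all maps share one [0, 1]
  scale and the most uncertain cell reads exactly 1.  (On the reference
  data that shared divisor was 0.38.)

Rasters are written as ESRI ASCII grids (plain text, georeferencing in the
header) with a JSON sidecar carrying the CRS label and any metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as ft
from .grid import GridSpec
from .model import EnsembleModel

__all__ = [
    "MappingError",
    "RiskMapStack",
    "scenario_predictions",
    "summarize_maps",
    "normalize_uncertainty",
    "write_raster",
    "read_raster",
]

NODATA = -9999.0


class MappingError(ValueError):
    """Invalid mapping inputs (missing scenario weather, shape mismatch)."""


@dataclass
class RiskMapStack:
    """Per-member x per-scenario establishment probabilities on the grid.

    ``probs`` has shape (n_members, n_scenarios, n_rows, n_cols); cells
    outside the region mask hold NaN.
    """

    grid: GridSpec
    scenario_years: tuple[int, ...]
    probs: np.ndarray

    @property
    def depth(self) -> int:
        return self.probs.shape[0] * self.probs.shape[1]

    def yearly_mean_maps(self) -> dict[int, np.ndarray]:
        """Mean over members, one map per scenario year."""
        return {
            year: self.probs[:, i].mean(axis=0)
            for i, year in enumerate(self.scenario_years)
        }

    def yearly_sd_maps(self) -> dict[int, np.ndarray]:
        """Population SD over members, one map per scenario year."""
        return {
            year: self.probs[:, i].std(axis=0, ddof=0)
            for i, year in enumerate(self.scenario_years)
        }

    def summary_mean_map(self) -> np.ndarray:
        """Mean over all member x scenario predictions."""
        return self.probs.reshape(self.depth, *self.probs.shape[2:]).mean(axis=0)

    def summary_sd_map(self) -> np.ndarray:
        """Population SD over all member x scenario predictions."""
        return self.probs.reshape(self.depth, *self.probs.shape[2:]).std(axis=0, ddof=0)


def scenario_predictions(
    ensemble: EnsembleModel,
    static_layers: pd.DataFrame,
    weather: pd.DataFrame,
    scenarios: Sequence[int],
    distance_layer: np.ndarray | Mapping[tuple[int, int], float],
    grid: GridSpec,
    cells: Sequence[tuple[int, int]] | None = None,
) -> RiskMapStack:
    """Predict establishment probability per member and weather scenario.

    For each scenario year the feature matrix is rebuilt (that year's
    meteorology, the static layers, the supplied dispersal-distance layer)
    and every member predicts through its own normalization bounds.

    ``distance_layer`` is the car-distance feature: a constant layer for
    extrapolation regions, a point-seeded layer, or distances from prior
    establishment data.
    """
    scenarios = tuple(scenarios)
    if not scenarios:
        raise MappingError("at least one scenario year is required")
    if cells is None:
        cells = grid.all_cells()
    probs = np.full(
        (len(ensemble.members), len(scenarios), grid.n_rows, grid.n_cols), np.nan
    )
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    for s_i, year in enumerate(scenarios):
        try:
            X = ft.build_feature_matrix(cells, year, weather, static_layers, distance_layer)
        except ft.FeatureError as exc:
            raise MappingError(f"scenario year {year}: {exc}") from exc
        for m_i, member in enumerate(ensemble.members):
            probs[m_i, s_i, rows, cols] = member.predict_proba(X)
    return RiskMapStack(grid=grid, scenario_years=scenarios, probs=probs)


def summarize_maps(
    stack: RiskMapStack,
) -> tuple[dict[int, np.ndarray], np.ndarray, dict[str, np.ndarray]]:
    """Yearly mean maps, the summary mean map, and all raw SD maps.

    The SD dict holds one map per scenario year (SD over members, keyed by
    the year as a string) plus the ``"summary"`` map (SD over the full
    member x scenario stack).
    """
    if stack.probs.size == 0:
        raise MappingError("empty prediction stack")
    yearly = stack.yearly_mean_maps()
    sd_maps: dict[str, np.ndarray] = {
        str(year): m for year, m in stack.yearly_sd_maps().items()
    }
    sd_maps["summary"] = stack.summary_sd_map()
    return yearly, stack.summary_mean_map(), sd_maps


def normalize_uncertainty(
    sd_maps: Mapping[str, np.ndarray] | Sequence[np.ndarray],
) -> tuple[dict[str, np.ndarray] | list[np.ndarray], float]:
    """Jointly min-max normalize raw SD maps to a shared [0, 1] scale.

    The divisor is the global maximum raw SD over every supplied map
    (NaN/no-data cells excluded); all-zero input returns unchanged maps
    with divisor 0.  Returns ``(normalized maps, divisor)``.
    """
    if isinstance(sd_maps, Mapping):
        items = list(sd_maps.items())
        arrays = [np.asarray(m, float) for _, m in items]
    else:
        items = None
        arrays = [np.asarray(m, float) for m in sd_maps]
    if not arrays:
        raise MappingError("need at least one raw SD map")
    divisor = float(max(np.nanmax(a) if np.isfinite(a).any() else 0.0 for a in arrays))
    if divisor > 0:
        normalized = [a / divisor for a in arrays]
    else:
        normalized = [a.copy() for a in arrays]
    if items is not None:
        return {k: n for (k, _), n in zip(items, normalized)}, divisor
    return normalized, divisor


def write_raster(
    map_values: np.ndarray,
    path: str | Path,
    grid: GridSpec,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a grid-aligned map as an ESRI ASCII raster (.asc).

    Row 0 of ``map_values`` is the southernmost row (grid convention);
    the ASCII format stores rows north-to-south, so rows are flipped on
    write and restored on read.  NaN cells become the declared NODATA
    value.  A JSON sidecar (``<path>.aux.json``) records the CRS label and
    caller metadata.
    """
    arr = np.asarray(map_values, float)
    if arr.shape != (grid.n_rows, grid.n_cols):
        raise MappingError(
            f"map shape {arr.shape} does not match grid ({grid.n_rows}, {grid.n_cols})"
        )
    arr32 = np.where(np.isnan(arr), NODATA, arr).astype(np.float32)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in arr32[::-1]:  # north to south
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")
    sidecar = {"crs_label": grid.crs_label, **(dict(metadata) if metadata else {})}
    path.with_suffix(path.suffix + ".aux.json").write_text(json.dumps(sidecar, indent=2))


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec, dict]:
    """Read an ESRI ASCII raster written by :func:`write_raster`.

    Returns (values, grid, metadata) with NODATA cells restored to NaN.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, value = line.split()
        header[key.lower()] = float(value)
    values = np.loadtxt(lines[6:], dtype=np.float64)
    values = np.atleast_2d(values)[::-1].copy()  # back to south-first rows
    nodata = header.get("nodata_value", NODATA)
    values[values == nodata] = np.nan
    sidecar_path = path.with_suffix(path.suffix + ".aux.json")
    metadata = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
        crs_label=str(metadata.get("crs_label", "unknown")),
    )
    return values, grid, metadata
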