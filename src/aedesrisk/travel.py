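"""Car-distance-to-establishment: travel-time dispersal feature.

Adult tiger mosquitoes hitchhike in vehicles, so proximity to an already
established population along the road network — not straight-line distance
— predicts where new populations appear.  The feature for cell ``c`` in
year ``y`` is the minimum travel time in minutes from any cell established
in year ``y-1`` to ``c``.

Travel times come from a pluggable provider.  The synthetic provider is
shortest-path travel on the 4-connected grid graph with per-edge minutes
drawn once at world creation; a precomputed-matrix provider covers
externally supplied times.  (A production deployment would adapt a road
routing engine behind the same contract.)  The contract is directional —
min over sources of time(source -> cell) — although the grid provider is
symmetric.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import GridSpec, GridError

__all__ = [
    "TravelTimeProvider",
    "GridTravelProvider",
    "MatrixTravelProvider",
    "TravelError",
    "car_distance_to_establishment",
    "fixed_distance_layer",
    "point_distance_layer",
]


class TravelError(ValueError):
    """Invalid travel-feature request (empty source set, bad points)."""


class TravelTimeProvider:
    """Contract: nonnegative travel time in minutes between grid cells."""

    grid: GridSpec

    def time(self, from_cell: tuple[int, int], to_cell: tuple[int, int]) -> float:
        raise NotImplementedError

    def times_from_set(self, sources: Sequence[tuple[int, int]]) -> np.ndarray:
        """Per-cell minimum time from any source, flat row-major array.

        Default implementation loops over sources; subclasses override
        with a vectorized computation.
        """
        grid = self.grid
        out = np.full(grid.n_cells, np.inf)
        for src in sources:
            for r in range(grid.n_rows):
                for c in range(grid.n_cols):
                    i = grid.cell_index(r, c)
                    out[i] = min(out[i], self.time(src, (r, c)))
        return out


class GridTravelProvider(TravelTimeProvider):
    """Shortest-path minutes on the 4-connected grid graph.

    Edge travel times (minutes per 200 m hop) are supplied per edge; the
    provider is symmetric and satisfies the triangle inequality by
    construction.
    """

    def __init__(self, grid: GridSpec, edges: pd.DataFrame):
        """``edges`` columns: cell_a, cell_b (flat row-major indices), minutes."""
        self.grid = grid
        if (edges["minutes"] < 0).any():
            raise TravelError("edge travel times must be nonnegative")
        n = grid.n_cells
        a = edges["cell_a"].to_numpy(int)
        b = edges["cell_b"].to_numpy(int)
        w = edges["minutes"].to_numpy(float)
        self._graph = coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([a, b]), np.concatenate([b, a]))),
            shape=(n, n),
        ).tocsr()
        self._edges = edges

    @property
    def edges(self) -> pd.DataFrame:
        return self._edges

    def time(self, from_cell: tuple[int, int], to_cell: tuple[int, int]) -> float:
        i = self.grid.cell_index(*from_cell)
        j = self.grid.cell_index(*to_cell)
        d = dijkstra(self._graph, indices=i)
        return float(d[j])

    def times_from_set(self, sources: Sequence[tuple[int, int]]) -> np.ndarray:
        idx = [self.grid.cell_index(*s) for s in sources]
        return dijkstra(self._graph, indices=idx, min_only=True)


class MatrixTravelProvider(TravelTimeProvider):
    """Provider backed by a precomputed dense (n_cells x n_cells) matrix."""

    def __init__(self, grid: GridSpec, matrix: np.ndarray):
        matrix = np.asarray(matrix, float)
        if matrix.shape != (grid.n_cells, grid.n_cells):
            raise TravelError(
                f"matrix shape {matrix.shape} does not match grid with {grid.n_cells} cells"
            )
        if (matrix < 0).any():
            raise TravelError("travel times must be nonnegative")
        self.grid = grid
        self._matrix = matrix

    def time(self, from_cell: tuple[int, int], to_cell: tuple[int, int]) -> float:
        return float(self._matrix[self.grid.cell_index(*from_cell), self.grid.cell_index(*to_cell)])

    def times_from_set(self, sources: Sequence[tuple[int, int]]) -> np.ndarray:
        idx = [self.grid.cell_index(*s) for s in sources]
        return self._matrix[idx, :].min(axis=0)

    @classmethod
    def from_csv(cls, grid: GridSpec, path) -> "MatrixTravelProvider":
        """Load a headerless dense minutes matrix (row-major cell order)."""
        return cls(grid, np.loadtxt(path, delimiter=","))


def car_distance_to_establishment(
    cells: Sequence[tuple[int, int]],
    established_prev_year: Sequence[tuple[int, int]],
    provider: TravelTimeProvider,
) -> np.ndarray:
    """Minutes from the nearest previously established cell, per requested cell.

    A cell that is itself in the established set gets 0.  The established
    set must be nonempty: years without prior establishment data need an
    explicit fallback (see :func:`fixed_distance_layer`) rather than a
    silent default.
    """
    established = list(established_prev_year)
    if not established:
        raise TravelError(
            "no cells established in the previous year; pass a fallback "
            "distance layer (e.g. fixed_distance_layer) explicitly"
        )
    all_times = provider.times_from_set(established)
    return np.array([all_times[provider.grid.cell_index(*c)] for c in cells], float)


def fixed_distance_layer(
    cells: Sequence[tuple[int, int]], minutes: float = 0.5
) -> np.ndarray:
    """Constant dispersal-distance layer for extrapolation regions.

    Outside the surveillance area no prior-year establishment is known; a
    fixed 0.5 min (30 s) assumes establishment has already occurred in the
    immediate neighborhood, yielding a "risk if introduced" map.
    """
    if minutes < 0:
        raise TravelError(f"minutes must be nonnegative, got {minutes}")
    return np.full(len(cells), float(minutes))


def point_distance_layer(
    cells: Sequence[tuple[int, int]],
    establishment_points: Sequence[tuple[float, float]],
    provider: TravelTimeProvider,
) -> np.ndarray:
    """Distance layer seeded by observed establishment points (x, y).

    Each point is binned to its grid cell; the layer is the per-cell
    minimum travel time from any point's cell.
    """
    if not len(establishment_points):
        raise TravelError("establishment_points must be nonempty")
    source_cells = []
    for x, y in establishment_points:
        try:
            source_cells.append(provider.grid.cell_of(x, y))
        except GridError as exc:
            raise GridError(f"establishment point ({x}, {y}) outside the grid") from exc
    return car_distance_to_establishment(cells, source_cells, provider)
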