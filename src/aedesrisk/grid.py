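"""Planar analysis grid.

The study region is rasterized into square cells (200 m by default).  Cell
membership uses half-open intervals ``[origin + k*s, origin + (k+1)*s)`` so a
point lying exactly on a boundary belongs to the cell on the greater-index
side.  Rows index the y axis, columns the x axis; ``(row, col) = (0, 0)`` is
the cell whose lower-left corner is the grid origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "GridError"]


class GridError(ValueError):
    """Invalid grid configuration or out-of-grid coordinates."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the square analysis grid.

    Parameters
    ----------
    origin_x, origin_y
        Planar coordinates (m) of the lower-left corner of cell (0, 0).
    cell_size
        Cell edge length in metres (200 m in the reference setting).
    n_cols, n_rows
        Grid dimensions.
    crs_label
        Free-text coordinate-system label carried through to raster output
        (a real Swiss deployment would use CH1903/LV03).
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 200.0
    n_cols: int = 40
    n_rows: int = 40
    crs_label: str = "synthetic-planar"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_cols < 1 or self.n_rows < 1:
            raise GridError(
                f"grid must have at least one cell, got {self.n_rows}x{self.n_cols}"
            )

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing the point, half-open binning."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((y - self.origin_y) / self.cell_size))
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise GridError(f"point ({x}, {y}) falls outside the grid")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        col = (x - self.origin_x) / self.cell_size
        row = (y - self.origin_y) / self.cell_size
        return 0 <= col < self.n_cols and 0 <= row < self.n_rows

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y + (row + 0.5) * self.cell_size,
        )

    def cell_index(self, row: int, col: int) -> int:
        """Flat index in row-major order."""
        return row * self.n_cols + col

    def all_cells(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]
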