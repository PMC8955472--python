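"""Dataset assembly: labels + landscape + weather -> modeling matrices.

Bridges the labeling and feature stages: for every requested year it
computes the car-distance feature from the previous year's established
cells, builds the 79-column feature matrix for the labeled cells of that
year, and stacks everything into the row-aligned (X, y, years) triple the
ensemble trainer consumes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .features import build_feature_matrix
from .travel import TravelTimeProvider, TravelError, car_distance_to_establishment

__all__ = ["assemble_dataset", "established_cells"]


def established_cells(labels: pd.DataFrame, year: int) -> list[tuple[int, int]]:
    """Cells labeled established in ``year``, as sorted (row, col) pairs."""
    sub = labels[(labels["year"] == year) & labels["established"]]
    return sorted(zip(sub["cell_row"].astype(int), sub["cell_col"].astype(int)))


def assemble_dataset(
    labels: pd.DataFrame,
    years: Sequence[int],
    weather: pd.DataFrame,
    static_layers: pd.DataFrame,
    provider: TravelTimeProvider,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Feature matrix, labels and year tags for the labeled cells of ``years``.

    For each year ``y`` the dispersal feature is the travel time from the
    cells labeled established in ``y-1`` — so ``labels`` must extend one
    year before ``min(years)`` with at least one established cell (the
    reference study used its first surveillance year only for this).
    """
    x_parts, y_parts, year_parts = [], [], []
    for year in sorted(years):
        year_labels = labels[labels["year"] == year]
        if year_labels.empty:
            continue
        prior = established_cells(labels, year - 1)
        if not prior:
            raise TravelError(
                f"no established cells labeled in {year - 1}, required to compute "
                f"the car-distance feature for {year}"
            )
        cells = list(zip(year_labels["cell_row"].astype(int), year_labels["cell_col"].astype(int)))
        dist = car_distance_to_establishment(cells, prior, provider)
        x_parts.append(build_feature_matrix(cells, year, weather, static_layers, dist))
        y_parts.append(year_labels["established"].to_numpy(bool))
        year_parts.append(np.full(len(cells), year, dtype=int))
    if not x_parts:
        raise ValueError(f"no labeled cells in years {list(years)}")
    X = pd.concat(x_parts, axis=0)
    return X, np.concatenate(y_parts), np.concatenate(year_parts)
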