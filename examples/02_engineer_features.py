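"""Build the 79-predictor feature matrix for a few cells of a synthetic world.

Generates a small landscape with daily weather, computes the full
predictor vector (terrain, land cover, population, seasonal and biweekly
weather statistics, travel distance) for three cells, and prints a
readable slice.
"""

import numpy as np

from aedesrisk import build_feature_catalog, build_feature_matrix, car_distance_to_establishment
from aedesrisk.grid import GridSpec
from aedesrisk.synthetic import SyntheticWorldConfig, generate_weather, generate_world

config = SyntheticWorldConfig(
    grid=GridSpec(n_rows=20, n_cols=20), years=(2004, 2005, 2006), n_traps=50, rng_seed=3
)
world = generate_world(config)
weather = generate_weather(world)

catalog = build_feature_catalog()
print(f"Predictor catalog: {len(catalog)} features")
for group, names in catalog.groups.items():
    print(f"  {group:13s} {len(names):3d}  e.g. {names[0]!r}")

cells = [(0, 5), (10, 10), (19, 19)]  # valley floor, mid-slope, high corner
dist = car_distance_to_establishment(cells, sorted(world.seed_cells()), world.travel)
X = build_feature_matrix(cells, 2005, weather, world.static_layers, dist)

show = [
    "elevation", "slope", "clc112", "population",
    "warm-s Tmean avg", "cold-s Tmax p25", "Tmin minimum biweekly average",
    "warm-s RAIN avg", "car distance to establishment",
]
print(f"\nSelected predictors for year 2005 ({len(cells)} cells):")
print(X[show].round(2).to_string())
print("\nRows are cells; meteorological columns come from the cell's 1 km met-cell,")
print("'car distance to establishment' is minutes of travel from last year's front.")
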