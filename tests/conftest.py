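"""Shared fixtures: synthetic worlds at two scales.

``small_world`` (20x20) keeps unit tests fast; ``default_study`` is the
full default configuration (40x40, eleven years) with a fitted ensemble,
shared session-wide because fitting the eight LASSO members is the most
expensive step in the suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aedesrisk.grid import GridSpec
from aedesrisk.model import EnsembleConfig, fit_ensemble
from aedesrisk.pipeline import assemble_dataset
from aedesrisk.synthetic import (
    SyntheticWorldConfig,
    generate_weather,
    generate_world,
    simulate_establishment,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticWorldConfig:
    return SyntheticWorldConfig(
        grid=GridSpec(n_rows=20, n_cols=20),
        years=tuple(range(2004, 2010)),
        n_traps=120,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def small_weather(small_world):
    return generate_weather(small_world)


@pytest.fixture(scope="session")
def small_truth_slats(small_world, small_weather):
    return simulate_establishment(small_world, small_weather)


@pytest.fixture(scope="session")
def default_study():
    """Default 40x40 world with truth labels, dataset and fitted ensemble."""
    config = SyntheticWorldConfig(rng_seed=1)
    world = generate_world(config)
    weather = generate_weather(world)
    truth, slats = simulate_establishment(world, weather)
    years = sorted(config.years)
    model_years = years[1:]  # first year seeds the dispersal feature only
    X, y, yrs = assemble_dataset(truth, model_years, weather, world.static_layers, world.travel)
    train_years = tuple(model_years[:-2])
    train_mask = np.isin(yrs, train_years)
    ensemble = fit_ensemble(
        X[train_mask], y[train_mask], yrs[train_mask],
        EnsembleConfig(C=0.1, train_years=train_years, rng_seed=1),
    )
    return {
        "config": config,
        "world": world,
        "weather": weather,
        "truth": truth,
        "slats": slats,
        "X": X,
        "y": y,
        "years": yrs,
        "train_mask": train_mask,
        "train_years": train_years,
        "test_years": tuple(model_years[-2:]),
        "ensemble": ensemble,
    }


def make_slats(
    positives,
    analyzed=None,
    trap_id="T1",
    year=2010,
    start="2010-05-21",
    step_days=14,
) -> pd.DataFrame:
    """Build a slat table from boolean sequences, biweekly collection dates."""
    n = len(positives)
    analyzed = [True] * n if analyzed is None else list(analyzed)
    dates = pd.date_range(start, periods=n, freq=f"{step_days}D")
    return pd.DataFrame(
        {
            "trap_id": trap_id,
            "year": year,
            "collection_date": dates,
            "analyzed": analyzed,
            "positive": [bool(p) and a for p, a in zip(positives, analyzed)],
        }
    )
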