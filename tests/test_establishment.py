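"""Establishment labeling: periods, run detection, cell aggregation, bookkeeping."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aedesrisk.datasets import TICINO_TEST_YEARS, TICINO_TRAIN_YEARS, load_ticino_summary
from aedesrisk.establishment import (
    LabelingError,
    assign_period,
    cell_labels,
    dataset_summary,
    label_traps,
    split_counts,
    trap_establishment,
    train_test_split,
)
from aedesrisk.grid import GridError, GridSpec

from conftest import make_slats


# --- biweekly periods ------------------------------------------------------

@pytest.mark.parametrize(
    "date,expected",
    [
        ("2010-05-20", 1),    # ISO week 20 opens the season
        ("2010-05-27", 1),    # ISO week 21 still period 1
        ("2010-09-30", 10),   # ISO week 39 closes the season
        ("2010-03-10", None), # ISO week 10: outside the season
        ("2010-12-25", None),
    ],
)
def test_assign_period_season_boundaries(date, expected):
    assert assign_period(date) == expected


def test_periods_cover_weeks_20_to_39_in_pairs():
    # every ISO week 20..39 maps to a period; weeks pair up 2 per period
    weeks = pd.date_range("2011-01-01", "2011-12-31", freq="D")
    periods = {}
    for d in weeks:
        p = assign_period(d)
        if p is not None:
            periods.setdefault(p, set()).add(d.isocalendar().week)
    assert sorted(periods) == list(range(1, 11))
    assert all(len(ws) == 2 for ws in periods.values())


# --- trap-year establishment rule ------------------------------------------

def brute_force_established(positives, analyzed, dates, threshold=28, strict=False):
    """Oracle: scan every contiguous all-positive block of analyzed slats."""
    seq = [(d, p) for d, p, a in zip(dates, positives, analyzed) if a]
    seq.sort(key=lambda t: t[0])
    for i in range(len(seq)):
        for j in range(i, len(seq)):
            block = seq[i : j + 1]
            if all(p for _, p in block):
                span = (block[-1][0] - block[0][0]).days
                if span > threshold if strict else span >= threshold:
                    return True
    return False


@pytest.mark.parametrize(
    "positives,expected",
    [
        ([1, 1, 1], True),      # days 0/14/28: span 28 >= 28
        ([1, 1], False),        # span 14
        ([1, 0, 1, 0, 1], False),  # alternating: every run spans 0 days
        ([0, 1, 1, 1, 0], True),
    ],
)
def test_trap_establishment_biweekly_examples(positives, expected):
    established, _ = trap_establishment(make_slats(positives))
    assert established is expected


def test_alternate_round_two_positives_default_vs_strict():
    # analyzed slats 28 days apart: two consecutive positives span exactly 28
    slats = make_slats([1, 1], step_days=28)
    assert trap_establishment(slats)[0] is True
    assert trap_establishment(slats, strict=True)[0] is False


def test_unanalyzed_slats_are_invisible_but_negatives_break_runs():
    # positive, unanalyzed, positive: one run spanning 28 days
    s = make_slats([1, 0, 1], analyzed=[True, False, True])
    assert trap_establishment(s)[0] is True
    # an analyzed negative in between breaks the run
    s2 = make_slats([1, 0, 1], analyzed=[True, True, True])
    assert trap_establishment(s2)[0] is False


def test_run_enumeration_oracle_all_short_sequences():
    """Exhaustive check against the brute-force oracle on all sequences up to 12 slats."""
    dates = list(pd.date_range("2010-05-21", periods=12, freq="14D"))
    for n in range(1, 13):
        for bits in itertools.product([0, 1], repeat=n):
            slats = make_slats(list(bits))
            got, _ = trap_establishment(slats)
            want = brute_force_established(list(bits), [True] * n, dates[:n])
            assert got == want, f"mismatch on {bits}"


@settings(deadline=None, max_examples=150, derandomize=True)
@given(
    bits=st.lists(st.booleans(), min_size=1, max_size=10),
    analyzed=st.lists(st.booleans(), min_size=10, max_size=10),
    strict=st.booleans(),
)
def test_run_oracle_with_unanalyzed_slats(bits, analyzed, strict):
    n = len(bits)
    ana = analyzed[:n]
    slats = make_slats(bits, analyzed=ana)
    dates = list(pd.date_range("2010-05-21", periods=n, freq="14D"))
    got, _ = trap_establishment(slats, strict=strict)
    assert got == brute_force_established(
        [b and a for b, a in zip(bits, ana)], ana, dates, strict=strict
    )


@settings(deadline=None, max_examples=100, derandomize=True)
@given(bits=st.lists(st.booleans(), min_size=2, max_size=10), flip=st.integers(0, 9))
def test_flipping_negative_to_positive_is_monotone(bits, flip):
    """Turning any slat positive can only move a trap toward establishment."""
    flip = flip % len(bits)
    before, _ = trap_establishment(make_slats(bits))
    flipped = list(bits)
    flipped[flip] = True
    after, _ = trap_establishment(make_slats(flipped))
    assert after or not before


def test_duplicate_collection_dates_rejected():
    s = make_slats([1, 1])
    s.loc[1, "collection_date"] = s.loc[0, "collection_date"]
    with pytest.raises(LabelingError, match="duplicate"):
        trap_establishment(s)


def test_egg_count_overrides_positive_flag():
    s = make_slats([1, 1, 1])
    s["egg_count"] = [5, 0, 7]  # middle slat actually empty
    assert trap_establishment(s)[0] is False


# --- cell labels ------------------------------------------------------------

def _trap_results(rows):
    return pd.DataFrame(rows, columns=["trap_id", "year", "analyzed_any", "established"])


def test_cell_established_if_any_trap_is():
    grid = GridSpec(n_rows=2, n_cols=2, cell_size=100)
    traps = pd.DataFrame({"trap_id": ["A", "B"], "x": [10.0, 20.0], "y": [10.0, 20.0]})
    results = _trap_results([("A", 2010, True, False), ("B", 2010, True, True)])
    labels = cell_labels(results, traps, grid)
    assert len(labels) == 1
    assert bool(labels["established"].iloc[0]) is True


def test_trap_year_without_analyzed_slats_is_unobserved():
    grid = GridSpec(n_rows=2, n_cols=2, cell_size=100)
    traps = pd.DataFrame({"trap_id": ["A"], "x": [10.0], "y": [10.0]})
    results = _trap_results([("A", 2010, False, False)])
    assert cell_labels(results, traps, grid).empty


def test_trap_on_boundary_goes_to_higher_cell():
    grid = GridSpec(n_rows=2, n_cols=2, cell_size=100)
    traps = pd.DataFrame({"trap_id": ["A"], "x": [100.0], "y": [100.0]})
    results = _trap_results([("A", 2010, True, True)])
    labels = cell_labels(results, traps, grid)
    assert (labels["cell_row"].iloc[0], labels["cell_col"].iloc[0]) == (1, 1)


def test_trap_outside_grid_names_the_trap():
    grid = GridSpec(n_rows=2, n_cols=2, cell_size=100)
    traps = pd.DataFrame({"trap_id": ["Z9"], "x": [999.0], "y": [10.0]})
    with pytest.raises(GridError, match="Z9"):
        cell_labels(_trap_results([("Z9", 2010, True, True)]), traps, grid)


# --- bookkeeping ------------------------------------------------------------

def test_reference_surveillance_totals():
    """The published yearly table reconciles with the printed split totals."""
    summary = load_ticino_summary()
    counts = split_counts(summary, TICINO_TRAIN_YEARS, TICINO_TEST_YEARS)
    assert counts["total_records"] == 7268
    assert counts["train_cells"] == 4282
    assert counts["train_established"] == 990
    assert counts["train_non_established"] == 3292
    assert counts["test_cells"] == 2961
    assert counts["test_established"] == 1608
    assert counts["test_non_established"] == 1353


def test_reference_table_2012_column():
    summary = load_ticino_summary().set_index("year")
    assert summary.loc[2012, "cells_observed"] == 1017
    assert summary.loc[2012, "cells_established"] == 466


def test_dataset_summary_matches_brute_recount(small_world, small_truth_slats):
    truth, slats = small_truth_slats
    trap_results = label_traps(slats)
    labels = cell_labels(trap_results, small_world.traps, small_world.grid)
    summary = dataset_summary(labels, trap_results)
    # independent recount from the raw tables
    for _, row in summary.iterrows():
        year = row["year"]
        tr = trap_results[(trap_results["year"] == year) & trap_results["analyzed_any"]]
        assert row["ovitraps_analyzed"] == len(tr)
        assert row["ovitraps_established"] == int(tr["established"].sum())
        lb = labels[labels["year"] == year]
        assert row["cells_observed"] == len(lb)
        assert row["cells_established"] == int(lb["established"].sum())
    assert (summary["ovitraps_established"] <= summary["ovitraps_analyzed"]).all()
    assert (summary["cells_established"] <= summary["cells_observed"]).all()


def test_dataset_summary_empty():
    empty_labels = pd.DataFrame(columns=["cell_row", "cell_col", "year", "established"])
    empty_results = pd.DataFrame(columns=["trap_id", "year", "analyzed_any", "established"])
    assert dataset_summary(empty_labels, empty_results).empty


def test_train_test_split_partitions(small_world, small_truth_slats):
    truth, slats = small_truth_slats
    trap_results = label_traps(slats)
    labels = cell_labels(trap_results, small_world.traps, small_world.grid)
    years = sorted(labels["year"].unique())
    train, test = train_test_split(labels, years[:-2], years[-2:])
    assert len(train) + len(test) == len(labels)
    key = ["cell_row", "cell_col", "year"]
    merged = train.merge(test, on=key)
    assert merged.empty  # no (cell, year) in both

    with pytest.raises(LabelingError, match="overlap"):
        train_test_split(labels, years[:2], years[1:3])

    train_only, empty = train_test_split(labels, years, [])
    assert len(train_only) == len(labels) and empty.empty
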