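"""Feature engineering: catalog, seasonal stats, biweekly extremes, normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aedesrisk import features as ft


# --- season windows ---------------------------------------------------------

def test_warm_season_is_may_through_september():
    w = ft.season_window(2010, "warm")
    assert (w.start, w.end) == (pd.Timestamp("2010-05-01"), pd.Timestamp("2010-09-30"))
    assert w.n_days == 153


def test_cold_season_spans_previous_december():
    c = ft.season_window(2010, "cold")
    assert (c.start, c.end) == (pd.Timestamp("2009-12-01"), pd.Timestamp("2010-02-28"))


def test_cold_season_leap_year_ends_feb_29():
    assert ft.season_window(2012, "cold").end == pd.Timestamp("2012-02-29")


# --- seasonal statistics ----------------------------------------------------

def _daily(values, start):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(values, index=idx)


def test_constant_series_all_stats_equal_constant():
    w = ft.season_window(2010, "warm")
    s = _daily(np.full(w.n_days, 10.0), w.start)
    stats = ft.seasonal_statistics(s, w, "Tmean")
    assert set(stats) == {f"warm-s Tmean {q}" for q in ("avg", "p5", "p25", "p75", "p95")}
    assert all(v == 10.0 for v in stats.values())


def test_rain_emits_only_three_stats():
    w = ft.season_window(2010, "warm")
    s = _daily(np.linspace(0, 5, w.n_days), w.start)
    stats = ft.seasonal_statistics(s, w, "RAIN")
    assert set(stats) == {"warm-s RAIN avg", "warm-s RAIN p75", "warm-s RAIN p95"}


def test_percentiles_match_sort_and_interpolate_oracle():
    """Linear interpolation between order statistics, checked by hand."""
    w = ft.season_window(2010, "warm")
    values = np.arange(1.0, w.n_days + 1)  # 1..153
    rng = np.random.default_rng(3)
    rng.shuffle(values)
    stats = ft.seasonal_statistics(_daily(values, w.start), w, "Tmin")
    srt = np.sort(values)
    n = len(srt)
    for q in (5, 25, 75, 95):
        pos = (n - 1) * q / 100.0
        lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
        oracle = srt[lo] + frac * (srt[min(lo + 1, n - 1)] - srt[lo])
        assert stats[f"warm-s Tmin p{q}"] == pytest.approx(oracle)
    assert stats["warm-s Tmin avg"] == pytest.approx(values.mean())


def test_quantiles_are_monotone_on_random_series():
    w = ft.season_window(2011, "cold")
    rng = np.random.default_rng(5)
    for _ in range(10):
        s = _daily(rng.normal(0, 8, w.n_days), w.start)
        stats = ft.seasonal_statistics(s, w, "Tmax")
        assert (
            stats["cold-s Tmax p5"]
            <= stats["cold-s Tmax p25"]
            <= stats["cold-s Tmax p75"]
            <= stats["cold-s Tmax p95"]
        )


def test_missing_days_error_lists_gap():
    w = ft.season_window(2010, "warm")
    s = _daily(np.zeros(w.n_days), w.start).drop(pd.Timestamp("2010-06-15"))
    with pytest.raises(ft.FeatureError, match="2010-06-15"):
        ft.seasonal_statistics(s, w, "Tmean")


# --- biweekly extremes ------------------------------------------------------

def _year_series(values, year):
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    assert len(values) == len(idx)
    return pd.Series(values, index=idx)


def brute_biweekly(values, how, agg):
    """Oracle: loop over every full 14-day window."""
    outs = []
    for i in range(len(values) - 13):
        w = values[i : i + 14]
        outs.append(np.mean(w) if how == "mean" else (np.min(w) if how == "min" else np.max(w)))
    return min(outs) if agg == "min" else max(outs)


def test_constant_series_biweekly_features_equal_constant():
    year = 2010
    n = 365
    const = _year_series(np.full(n, 4.5), year)
    warm = ft.season_window(year, "warm")
    rain = pd.Series(np.full(warm.n_days, 4.5), index=warm.dates())
    feats = ft.biweekly_extremes(const, const, rain, year)
    assert all(v == pytest.approx(4.5) for v in feats.values())


def test_cold_spell_block_is_found():
    year = 2010
    tmin = np.full(365, 10.0)
    tmin[40:54] = -5.0  # one exact 14-day cold block
    s = _year_series(tmin, year)
    warm = ft.season_window(year, "warm")
    rain = pd.Series(np.zeros(warm.n_days), index=warm.dates())
    feats = ft.biweekly_extremes(s, s, rain, year)
    assert feats["Tmin minimum biweekly average"] == pytest.approx(-5.0)
    assert feats["Tmin minimum biweekly maximum"] == pytest.approx(-5.0)


def test_all_dry_warm_season_rain_features_zero():
    year = 2011
    t = _year_series(np.full(365, 15.0), year)
    warm = ft.season_window(year, "warm")
    rain = pd.Series(np.zeros(warm.n_days), index=warm.dates())
    feats = ft.biweekly_extremes(t, t, rain, year)
    assert feats["warm-s RAIN maximum biweekly average"] == 0.0
    assert feats["warm-s RAIN minimum biweekly average"] == 0.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_biweekly_features_match_window_scan_oracle(seed):
    year = 2013
    rng = np.random.default_rng(seed)
    tmin = _year_series(rng.normal(2, 6, 365), year)
    tmax = _year_series(rng.normal(16, 6, 365), year)
    warm = ft.season_window(year, "warm")
    rain = pd.Series(rng.gamma(0.5, 6, warm.n_days) * (rng.random(warm.n_days) < 0.4),
                     index=warm.dates())
    feats = ft.biweekly_extremes(tmin, tmax, rain, year)
    tv, xv, rv = tmin.to_numpy(), tmax.to_numpy(), rain.to_numpy()
    assert feats["Tmin minimum biweekly maximum"] == pytest.approx(brute_biweekly(tv, "max", "min"))
    assert feats["Tmin minimum biweekly average"] == pytest.approx(brute_biweekly(tv, "mean", "min"))
    assert feats["Tmax maximum biweekly minimum"] == pytest.approx(brute_biweekly(xv, "min", "max"))
    assert feats["Tmax maximum biweekly average"] == pytest.approx(brute_biweekly(xv, "mean", "max"))
    assert feats["warm-s RAIN maximum biweekly average"] == pytest.approx(brute_biweekly(rv, "mean", "max"))
    assert feats["warm-s RAIN minimum biweekly average"] == pytest.approx(brute_biweekly(rv, "mean", "min"))
    # dry-vs-wet fortnight ordering always holds
    assert feats["warm-s RAIN minimum biweekly average"] <= feats["warm-s RAIN maximum biweekly average"]


# --- catalog ----------------------------------------------------------------

def test_catalog_cardinalities():
    cat = ft.build_feature_catalog()
    assert len(cat) == 79
    assert len(cat.groups["terrain"]) == 3
    assert len(cat.groups["land_cover"]) == 32
    assert len(cat.groups["population"]) == 1
    assert len(cat.groups["met_seasonal"]) == 36
    assert len(cat.groups["met_biweekly"]) == 6
    assert len(cat.groups["travel"]) == 1
    assert len(set(cat.names)) == 79  # no duplicates
    assert "clc121" in cat.names and ft.CAR_DISTANCE in cat.names


def test_catalog_is_deterministic():
    assert ft.build_feature_catalog().names == ft.build_feature_catalog().names


def test_validate_names_rejects_unknown():
    with pytest.raises(ft.FeatureError, match="not-a-feature"):
        ft.build_feature_catalog().validate_names(["elevation", "not-a-feature"])


# --- feature matrix ---------------------------------------------------------

def test_feature_matrix_has_79_columns_in_catalog_order(small_world, small_weather):
    cells = [(0, 0), (3, 7), (19, 19)]
    X = ft.build_feature_matrix(cells, 2006, small_weather, small_world.static_layers,
                                np.array([1.0, 2.0, 3.0]))
    assert tuple(X.columns) == ft.build_feature_catalog().names
    assert len(X) == 3
    assert not X.isna().any().any()


def test_cells_in_same_met_cell_share_meteorology(small_world, small_weather):
    # (0,0) and (1,1) are in the same 5x5 met block; (0,9) is not
    cells = [(0, 0), (1, 1), (0, 9)]
    X = ft.build_feature_matrix(cells, 2007, small_weather, small_world.static_layers,
                                np.zeros(3))
    met_cols = list(ft.build_feature_catalog().groups["met_seasonal"])
    assert X.iloc[0][met_cols].equals(X.iloc[1][met_cols])
    assert not X.iloc[0][met_cols].equals(X.iloc[2][met_cols])


def test_feature_matrix_entries_match_independent_recomputation(small_world, small_weather):
    """Each entry equals a from-scratch recomputation on the raw daily records."""
    cell = (4, 6)
    year = 2008
    static = small_world.static_layers.set_index(["cell_row", "cell_col"])
    X = ft.build_feature_matrix([cell], year, small_weather, small_world.static_layers,
                                np.array([7.25]))
    row = X.iloc[0]
    assert row["elevation"] == static.loc[cell, "elevation"]
    assert row["population"] == static.loc[cell, "population"]
    assert row[ft.CAR_DISTANCE] == 7.25
    mc = static.loc[cell, "met_cell"]
    w = small_weather[small_weather["met_cell"] == mc].set_index("date").sort_index()
    warm = ft.season_window(year, "warm")
    warm_tmean = w.loc[warm.start : warm.end, "tmean"].to_numpy()
    assert row["warm-s Tmean avg"] == pytest.approx(warm_tmean.mean())
    assert row["warm-s Tmean p95"] == pytest.approx(np.percentile(warm_tmean, 95))
    cold = ft.season_window(year, "cold")
    cold_rain = w.loc[cold.start : cold.end, "rain"].to_numpy()
    assert row["cold-s RAIN p75"] == pytest.approx(np.percentile(cold_rain, 75))
    year_tmin = w.loc[f"{year}-01-01" : f"{year}-12-31", "tmin"].to_numpy()
    assert row["Tmin minimum biweekly average"] == pytest.approx(
        brute_biweekly(year_tmin, "mean", "min")
    )


def test_missing_met_cell_mapping_errors(small_world, small_weather):
    static = small_world.static_layers.drop(columns=["met_cell"])
    with pytest.raises(ft.FeatureError, match="met_cell"):
        ft.build_feature_matrix([(0, 0)], 2006, small_weather, static, np.zeros(1))


# --- normalization ----------------------------------------------------------

def test_min_max_normalization_arithmetic():
    train = pd.DataFrame({"a": [0.0, 10.0], "b": [5.0, 5.0]})
    bounds = ft.fit_normalizer(train)
    out = ft.apply_normalizer(bounds, pd.DataFrame({"a": [5.0], "b": [5.0]}))
    assert out["a"].iloc[0] == 0.5
    assert out["b"].iloc[0] == 0.0  # constant feature maps to 0


def test_values_beyond_training_range_are_not_clipped():
    train = pd.DataFrame({"a": [0.0, 10.0]})
    bounds = ft.fit_normalizer(train)
    out = ft.apply_normalizer(bounds, pd.DataFrame({"a": [15.0, -5.0]}))
    assert out["a"].iloc[0] == 1.5
    assert out["a"].iloc[1] == -0.5


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 1000), n=st.integers(2, 40), d=st.integers(1, 6))
def test_fit_then_apply_lands_in_unit_cube(seed, n, d):
    rng = np.random.default_rng(seed)
    train = pd.DataFrame(rng.normal(0, 100, (n, d)), columns=[f"f{i}" for i in range(d)])
    out = ft.apply_normalizer(ft.fit_normalizer(train), train)
    assert (out.to_numpy() >= -1e-12).all() and (out.to_numpy() <= 1 + 1e-12).all()


def test_bounds_roundtrip_through_dict():
    train = pd.DataFrame({"a": [1.0, 2.0], "b": [-3.0, 4.0]})
    bounds = ft.fit_normalizer(train)
    restored = ft.NormalizationBounds.from_dict(bounds.to_dict())
    assert restored.names == bounds.names
    np.testing.assert_array_equal(restored.mins, bounds.mins)
    np.testing.assert_array_equal(restored.maxs, bounds.maxs)
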