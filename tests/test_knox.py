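"""Knox statistic, Monte-Carlo null replicates, and the lag-grid test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stclust import KnoxTest, close_pair_count, mc_null_replicate
from stclust.population import PopulationModel, PopulationSnapshot
from conftest import brute_close_pairs, random_case_table


def _uniform_population(extent=10_000.0, cell=1000.0, count=10):
    """Two identical flat snapshots (a static, spatially uniform population)."""
    xs = np.arange(cell / 2, extent, cell)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    cells = pd.DataFrame({"x": gx.ravel(), "y": gy.ravel(),
                          "child_count": np.full(gx.size, count)})
    return [
        PopulationSnapshot(date=pd.Timestamp("1990-01-01"), cells=cells, cell_size_m=cell),
        PopulationSnapshot(date=pd.Timestamp("2010-01-01"), cells=cells, cell_size_m=cell),
    ]


class TestClosePairCount:
    def test_single_case_has_no_pairs(self):
        df = random_case_table(np.random.default_rng(0), 1)
        count, pairs = close_pair_count(df, 1000.0, 730.0)
        assert count == 0 and len(pairs) == 0

    def test_collinear_chain_excludes_far_endpoints(self):
        df = pd.DataFrame(
            {
                "case_id": [1, 2, 3],
                "x_birth": [0.0, 600.0, 1200.0],
                "y_birth": [0.0, 0.0, 0.0],
                "birth_date": pd.to_datetime(["2000-01-01"] * 3),
                "diagnosis_date": pd.to_datetime(["2005-01-01"] * 3),
            }
        )
        count, pairs = close_pair_count(df, 1000.0, 730.0)
        assert count == 2
        assert {tuple(sorted(p)) for p in pairs} == {(0, 1), (1, 2)}

    def test_pairs_exactly_at_lag_are_excluded(self):
        df = pd.DataFrame(
            {
                "case_id": [1, 2, 3],
                "x_birth": [0.0, 1000.0, 0.0],
                "y_birth": [0.0, 0.0, 0.0],
                "birth_date": pd.to_datetime(["2000-01-01", "2000-01-01", "2001-12-31"]),
                "diagnosis_date": pd.to_datetime(["2005-01-01"] * 3),
            }
        )
        # case 2 at exactly s, case 3 at exactly t (730 d from 2000-01-01)
        count, _ = close_pair_count(df, 1000.0, 731.0)
        assert count == 1  # only the (1, 3) pair: d = 0 < s, dt = 730 < 731
        count, _ = close_pair_count(df, 1000.0, 730.0)
        assert count == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 120))
        df = random_case_table(rng, n, extent=4000.0, date_span=2000)
        s, t = float(rng.uniform(200, 3000)), float(rng.uniform(50, 1500))
        count, pairs = close_pair_count(df, s, t)
        oracle = brute_close_pairs(df, s, t)
        assert count == len(oracle)
        assert {tuple(sorted(p)) for p in pairs} == set(oracle)

    def test_nonpositive_lags_rejected(self):
        df = random_case_table(np.random.default_rng(0), 5)
        with pytest.raises(ValueError):
            close_pair_count(df, 0.0, 100.0)
        with pytest.raises(ValueError):
            close_pair_count(df, 100.0, -1.0)


class TestNullReplicate:
    def test_fixed_seed_gives_identical_replicate(self, small_registry):
        cases, pop = small_registry
        r1 = mc_null_replicate(cases, pop, seed=42)
        r2 = mc_null_replicate(cases, pop, seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_dates_and_covariates_carried_unchanged(self, small_registry):
        cases, pop = small_registry
        rep = mc_null_replicate(cases, pop, seed=1)
        pd.testing.assert_series_equal(rep["birth_date"], cases["birth_date"])
        pd.testing.assert_series_equal(rep["marker_positive"], cases["marker_positive"])
        assert not np.allclose(rep["x_birth"], cases["x_birth"])

    def test_degenerate_intensity_pins_all_locations_to_one_cell(self):
        pop = _uniform_population(extent=3000.0, cell=1000.0, count=0)
        for s in pop:
            s.cells.loc[4, "child_count"] = 100  # only the center cell populated
        df = random_case_table(np.random.default_rng(0), 50, extent=3000.0)
        rep = mc_null_replicate(df, pop, seed=0)
        cx, cy = pop[0].cells.loc[4, ["x", "y"]]
        assert (np.abs(rep["x_birth"] - cx) <= 500).all()
        assert (np.abs(rep["y_birth"] - cy) <= 500).all()

    def test_uniform_population_gives_uniform_replicate_locations(self):
        pop = _uniform_population(extent=10_000.0)
        df = random_case_table(np.random.default_rng(1), 400, extent=10_000.0)
        xs = np.concatenate(
            [mc_null_replicate(df, pop, seed=s)["x_birth"].to_numpy() for s in range(5)]
        )
        assert stats.kstest(xs / 10_000.0, "uniform").pvalue > 0.01

    def test_zero_total_intensity_is_a_data_error(self):
        pop = _uniform_population(count=0)
        df = random_case_table(np.random.default_rng(0), 5)
        with pytest.raises(ValueError, match="zero"):
            mc_null_replicate(df, pop, seed=0)


@pytest.fixture(scope="module")
def fitted(small_registry):
    cases, pop = small_registry
    return KnoxTest(n_replicates=199, random_state=5).fit(cases, pop)


class TestKnoxGrid:
    def test_counts_monotone_in_both_lags(self, fitted):
        for mat in (fitted.observed_, fitted.expected_):
            assert (np.diff(mat, axis=0) >= 0).all()
            assert (np.diff(mat, axis=1) >= 0).all()

    def test_p_values_in_valid_range(self, fitted):
        B = fitted.n_replicates
        assert ((fitted.p_mc_ >= 1.0 / (B + 1)) & (fitted.p_mc_ <= 1.0)).all()

    def test_adjusted_p_not_below_min_cell_p(self, fitted):
        assert fitted.adjusted_p_max_ >= fitted.min_p_

    def test_critical_lags_are_a_grid_point(self, fitted):
        s, t = fitted.critical_lags_
        assert s in fitted.spatial_lags_m and t in fitted.temporal_lags_days

    def test_observed_grid_matches_direct_pair_counts(self, small_registry, fitted):
        cases, _ = small_registry
        for _, row in fitted.grid_.iloc[::7].iterrows():
            count, _ = close_pair_count(cases, row["spatial_lag_m"],
                                        row["temporal_lag_days"])
            assert count == row["observed"]

    def test_replicate_count_floor_enforced(self, small_registry):
        cases, pop = small_registry
        with pytest.raises(ValueError):
            KnoxTest(n_replicates=50).fit(cases, pop)

    def test_lag_grids_must_increase(self, small_registry):
        cases, pop = small_registry
        with pytest.raises(ValueError):
            KnoxTest(spatial_lags_m=(1000.0, 500.0)).fit(cases, pop)

    def test_same_seed_reproduces_whole_result(self, small_registry):
        cases, pop = small_registry
        k1 = KnoxTest(n_replicates=99, random_state=9).fit(cases, pop)
        k2 = KnoxTest(n_replicates=99, random_state=9).fit(cases, pop)
        pd.testing.assert_frame_equal(k1.grid_, k2.grid_)
        assert k1.adjusted_p_max_ == k2.adjusted_p_max_


def test_strong_clustering_detected_at_design_lags():
    """Mini-epidemics of radius 500 m / 1 y should put the critical lags at or
    adjacent to (1 km, 12–24 months) in a majority of seeds."""
    from stclust import SimConfig, generate_cases, generate_population

    hits = 0
    n_seeds = 12
    for seed in range(n_seeds):
        cfg = SimConfig(n_cases=400, cluster_rate=25.0, cluster_radius_m=500.0,
                        cluster_duration_days=365.0, cluster_excess_cases=1,
                        sibling_pair_rate=0.0, seed=seed)
        pop = generate_population(cfg)
        cases = generate_cases(cfg, pop)
        kt = KnoxTest(n_replicates=99, random_state=seed).fit(cases, pop)
        s, t = kt.critical_lags_
        hits += s in (500.0, 1000.0, 2000.0) and t in (365.0, 548.0, 730.0)
    assert hits > n_seeds / 2
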