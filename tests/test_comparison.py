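"""Odds ratios, logistic comparison models, Monte-Carlo covariate p-values,
and Holm correction."""

import numpy as np
import pandas as pd
import pytest

from stclust import (ClusteredComparison, classify_clustered, fit_clustering_model,
                     holm_adjust, mc_covariate_pvalue, or_2x2)
from conftest import random_case_table


class TestOddsRatio2x2:
    @pytest.mark.parametrize(
        "a,b,c,d,expect_or,expect_ci",
        [
            # published registry contingency tables, reproduced to 2 decimals:
            (37, 56, 118, 358, 2.00, (1.26, 3.19)),   # marker-positive row
            (34, 75, 183, 355, 0.88, (0.56, 1.37)),   # high-hyperdiploidy row
            (15, 64, 103, 304, 0.69, (0.38, 1.27)),   # trisomy row
        ],
    )
    def test_registry_rows_to_two_decimals(self, a, b, c, d, expect_or, expect_ci):
        res = or_2x2(a, b, c, d)
        assert round(res.oddsratio, 2) == expect_or
        assert round(res.ci_low, 2) == expect_ci[0]
        assert round(res.ci_high, 2) == expect_ci[1]

    def test_balanced_table_is_symmetric_around_one(self):
        res = or_2x2(20, 20, 20, 20)
        assert res.oddsratio == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)

    def test_zero_cell_triggers_continuity_correction(self):
        with pytest.warns(UserWarning, match="continuity"):
            res = or_2x2(0, 10, 5, 20)
        assert res.corrected
        assert np.isfinite(res.oddsratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            or_2x2(-1, 2, 3, 4)

    def test_matches_logistic_fit_coefficient(self, rng):
        a, b, c, d = 30, 45, 80, 140
        y = np.r_[np.ones(a + b), np.zeros(c + d)]
        x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        df = pd.DataFrame({"exposed": np.where(x == 1, "yes", "no")})
        res = fit_clustering_model(df, y.astype(bool), "exposed", reference="no")
        table_or = res.table.loc[res.table["level"] == "yes", "oddsratio"].iloc[0]
        assert table_or == pytest.approx(or_2x2(a, b, c, d).oddsratio, abs=1e-6)


@pytest.fixture(scope="module")
def labeled(small_registry):
    cases, _ = small_registry
    return cases, classify_clustered(cases, 1000.0, 730.0)


class TestClusteringModel:
    def test_binary_characteristic_matches_2x2(self, labeled):
        cases, y = labeled
        res = fit_clustering_model(cases, y, "sex", reference="female")
        t = res.table.set_index("level")
        a = int(((cases["sex"] == "male") & y).sum())
        b = int(((cases["sex"] == "female") & y).sum())
        c = int(((cases["sex"] == "male") & ~y).sum())
        d = int(((cases["sex"] == "female") & ~y).sum())
        direct = or_2x2(a, b, c, d)
        assert t.loc["male", "oddsratio"] == pytest.approx(direct.oddsratio, abs=1e-6)
        assert t.loc["male", "ci_low"] == pytest.approx(direct.ci_low, abs=1e-6)

    def test_constant_density_term_reduces_to_unadjusted(self, labeled):
        cases, y = labeled
        unadj = fit_clustering_model(cases, y, "sex", reference="female")
        adj = fit_clustering_model(cases, y, "sex",
                                   density=np.full(len(cases), 1.234),
                                   reference="female")
        assert (adj.table["oddsratio"].iloc[1]
                == pytest.approx(unadj.table["oddsratio"].iloc[1], abs=1e-8))

    def test_missing_values_excluded_listwise(self, labeled):
        cases, y = labeled
        res = fit_clustering_model(cases, y, "marker_positive", reference="no")
        n_tested = (cases["marker_positive"] != "untested").sum()
        assert (res.table["N_clustered"].iloc[0]
                + res.table["N_nonclustered"].iloc[0]) == n_tested

    def test_single_level_characteristic_rejected(self, labeled):
        cases, y = labeled
        df = cases.copy()
        df["constant"] = "same"
        with pytest.raises(ValueError, match="levels"):
            fit_clustering_model(df, y, "constant")

    def test_perfect_separation_is_flagged(self):
        df = pd.DataFrame({"grp": ["a"] * 10 + ["b"] * 10})
        y = np.r_[np.ones(10), np.zeros(10)].astype(bool)
        with pytest.warns(UserWarning, match="separation"):
            res = fit_clustering_model(df, y, "grp", reference="a")
        assert res.separation_flagged


class TestHolm:
    def test_single_p_unchanged(self):
        res = holm_adjust([0.03])
        assert res.adjusted[0] == pytest.approx(0.03)

    def test_hand_evaluated_step_down(self):
        # (0.001, 0.02, 0.04): multiply by (3, 2, 1) then running max ->
        # (0.003, 0.04, 0.04)
        res = holm_adjust([0.001, 0.02, 0.04])
        np.testing.assert_allclose(res.adjusted, [0.003, 0.04, 0.04])

    def test_all_ones_stay_capped(self):
        res = holm_adjust([1.0, 1.0, 1.0])
        assert (res.adjusted == 1.0).all()

    def test_adjusted_never_below_raw_and_rejections_nested(self, rng):
        p = rng.uniform(0.001, 1.0, 12)
        res = holm_adjust(p, alpha=0.05)
        assert (res.adjusted >= res.raw - 1e-12).all()
        assert set(np.flatnonzero(res.reject)) <= set(np.flatnonzero(p <= 0.05))

    def test_empty_and_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([])
        with pytest.raises(ValueError):
            holm_adjust([0.5, 0.0])


class TestMCCovariate:
    def test_all_low_replicates_give_add_one_p(self, small_registry, monkeypatch):
        cases, pop = small_registry
        import stclust.comparison as comp

        stats_iter = iter([10.0] + [0.0] * 99)  # observed stat then 99 replicates

        def fake_lrt(y, cat):
            return next(stats_iter)

        monkeypatch.setattr(comp, "_lrt_stat", fake_lrt)
        p = comp.mc_covariate_pvalue(cases, pop, lambda x, y: np.where(x > 0, "a", "b"),
                                     1000.0, 730.0, n_replicates=99, random_state=0)
        assert p == pytest.approx(1.0 / 100.0)

    def test_deterministic_given_seed(self, small_registry):
        cases, pop = small_registry
        fn = lambda x, y: np.where(x < 25_000.0, "west", "east")  # noqa: E731
        p1 = mc_covariate_pvalue(cases, pop, fn, 1000.0, 730.0,
                                 n_replicates=99, random_state=11)
        p2 = mc_covariate_pvalue(cases, pop, fn, 1000.0, 730.0,
                                 n_replicates=99, random_state=11)
        assert p1 == p2

    def test_non_callable_covariate_rejected(self, small_registry):
        cases, pop = small_registry
        with pytest.raises(ValueError, match="callable"):
            mc_covariate_pvalue(cases, pop, "urban", 1000.0, 730.0)

    def test_location_covariate_p_roughly_uniform_under_null(self):
        """The MC chain should not over-reject a location-derived covariate
        generated under the null."""
        from stclust import SimConfig, generate_cases, generate_population

        ps = []
        fn = lambda x, y: np.where((x // 5000).astype(int) % 2 == 0, "a", "b")  # noqa: E731
        for seed in range(20):
            cfg = SimConfig(n_cases=150, cluster_rate=0.0, sibling_pair_rate=0.0,
                            seed=300 + seed)
            pop = generate_population(cfg)
            cases = generate_cases(cfg, pop)
            ps.append(mc_covariate_pvalue(cases, pop, fn, 1000.0, 730.0,
                                          n_replicates=99, random_state=seed))
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.2
        assert ps.mean() > 0.25


class TestComparisonTable:
    def test_full_table_layout_and_holm_column(self, small_registry):
        cases, _ = small_registry
        y = classify_clustered(cases, 1000.0, 730.0)
        comp = ClusteredComparison(
            {"sex": {"reference": "female"}, "urban": {"reference": "rural"},
             "age_group": {"reference": "1-5"}}
        ).fit(cases, y, density=None)
        tbl = comp.table_
        assert set(tbl["characteristic"]) == {"sex", "urban", "age_group"}
        first = ~tbl["characteristic"].duplicated()
        assert tbl.loc[first, "p_holm"].notna().all()
        assert (tbl.loc[first, "p_holm"] >= tbl.loc[first, "p_unadj"] - 1e-12).all()
        # counts never exceed their denominators
        assert (tbl["n_clustered"] <= tbl["N_clustered"]).all()
        assert (tbl["n_nonclustered"] <= tbl["N_nonclustered"]).all()
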