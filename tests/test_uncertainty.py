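import numpy as np
import pandas as pd
import pytest

from aitcea import (
    ALLERGOID,
    FIVE_GRASS,
    SYMPTOMATIC,
    ParameterDistribution,
    build_distributions,
    ceac,
    run_all_arms,
    run_psa,
    sample_psa,
    univariate_dsa,
)
from aitcea.uncertainty import EFFICACY_PREFIX, apply_draw, psa_summary


class TestDistributions:
    def test_beta_method_of_moments_identity(self):
        """Fitted beta reproduces the requested mean and SE."""
        d = ParameterDistribution("x", "beta", mean=0.29, se=0.058)
        a, b = d.shape_params()
        assert a / (a + b) == pytest.approx(0.29, abs=1e-9)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert var == pytest.approx(0.058**2, abs=1e-9)

    def test_gamma_method_of_moments_identity(self):
        d = ParameterDistribution("x", "gamma", mean=13.29, se=2.658)
        shape, scale = d.shape_params()
        assert shape * scale == pytest.approx(13.29, abs=1e-9)
        assert shape * scale**2 == pytest.approx(2.658**2, abs=1e-9)

    def test_twenty_percent_rule_applied(self, base_config):
        dists = {d.path: d for d in build_distributions(base_config)}
        visit = dists["costs.c_specialist_visit"]
        assert visit.family == "gamma"
        assert visit.se == pytest.approx(0.2 * 13.29, abs=1e-9)
        rr = dists["clinical.rr_asthma_ait"]
        assert rr.family == "normal"
        assert rr.se == pytest.approx(0.2 * 0.505, abs=1e-9)
        disc = dists[f"arms.{FIVE_GRASS}.disc_y1"]
        assert disc.family == "beta"
        assert disc.mean == 0.29

    def test_infeasible_beta_raises_naming_parameter(self):
        with pytest.raises(ValueError, match="u_near_one"):
            ParameterDistribution("u_near_one", "beta", mean=0.97, se=0.2 * 0.97)

    def test_supports_respected(self, base_config):
        rng_draws = sample_psa(build_distributions(base_config), 500, seed=11)
        for d in build_distributions(base_config):
            x = rng_draws[d.path]
            if d.family == "beta":
                assert ((x >= 0) & (x <= 1)).all()
            elif d.family == "gamma":
                assert (x >= 0).all()

    def test_sample_means_converge(self, base_config):
        """Sample means land within 3 MC SEs of the input means."""
        n = 1000
        draws = sample_psa(build_distributions(base_config), n, seed=3)
        for d in build_distributions(base_config):
            if d.se == 0:
                continue
            mc_se = d.se / np.sqrt(n)
            assert abs(draws[d.path].mean() - d.mean) < 3.5 * mc_se, d.path

    def test_seed_determinism(self, base_config):
        dists = build_distributions(base_config)
        a = sample_psa(dists, 100, seed=5)
        b = sample_psa(dists, 100, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestApplyDraw:
    def test_efficacy_path_sets_rtss_from_difference(self, base_config):
        cfg = apply_draw(base_config, {EFFICACY_PREFIX + FIVE_GRASS: 1.50}.items())
        assert cfg.arms[FIVE_GRASS].rtss == pytest.approx(4.47 - 1.50)
        # base config untouched
        assert base_config.arms[FIVE_GRASS].rtss == 3.26

    def test_mortality_ordering_repaired(self, base_config):
        cfg = apply_draw(base_config, {"clinical.p_death_all": 0.002}.items())
        assert cfg.clinical.p_death_asthma >= cfg.clinical.p_death_all

    def test_fixed_administration_months(self, base_config):
        """Under the PSA convention a season draw does not change the
        tablet's total administered months (acquisition price fixed)."""
        row = {"utility.season_months": 4.5}.items()
        cfg = apply_draw(base_config, row, fix_administration_months=True)
        assert cfg.arms[FIVE_GRASS].months_administered_per_year(
            cfg.utility.season_months
        ) == pytest.approx(7.0, abs=1e-12)
        cfg2 = apply_draw(base_config, row, fix_administration_months=False)
        assert cfg2.arms[FIVE_GRASS].months_administered_per_year(
            cfg2.utility.season_months
        ) == pytest.approx(8.5, abs=1e-12)


class TestPSA:
    def test_degenerate_variance_collapses_to_base_case(self, base_config, base_results):
        """All SEs zero: every draw reproduces the deterministic base case
        exactly."""
        dists = [
            ParameterDistribution(d.path, d.family, d.mean, 0.0, d.support)
            for d in build_distributions(base_config)
        ]
        draws = sample_psa(dists, 5, seed=1)
        psa = run_psa(base_config, draws, seed=1)
        for arm in (FIVE_GRASS, ALLERGOID, SYMPTOMATIC):
            assert (psa.costs[arm] == base_results[arm].costs.total_discounted).all()
            assert (psa.qalys[arm] == base_results[arm].qalys_discounted).all()

    def test_draw_count_and_reproducibility(self, base_config):
        dists = build_distributions(base_config)
        draws = sample_psa(dists, 50, seed=9)
        a = run_psa(base_config, draws, arms=(FIVE_GRASS, ALLERGOID), seed=9)
        b = run_psa(base_config, draws, arms=(FIVE_GRASS, ALLERGOID), seed=9)
        assert a.n_draws == 50
        pd.testing.assert_frame_equal(a.costs, b.costs)
        pd.testing.assert_frame_equal(a.qalys, b.qalys)

    def test_mean_incremental_qaly_near_base(self, base_config, base_results):
        """Under symmetric-ish input distributions the draw-wise mean of
        incremental QALYs sits within 2 MC SEs of the base case."""
        draws = sample_psa(build_distributions(base_config), 400, seed=21)
        psa = run_psa(base_config, draws, arms=(FIVE_GRASS, ALLERGOID), seed=21)
        inc = psa.incremental(FIVE_GRASS, ALLERGOID)["delta_qaly"]
        base_dq = (
            base_results[FIVE_GRASS].qalys_discounted
            - base_results[ALLERGOID].qalys_discounted
        )
        mc_se = inc.std() / np.sqrt(len(inc))
        assert abs(inc.mean() - base_dq) < 2.5 * mc_se

    def test_failures_counted_not_dropped(self, base_config):
        dists = build_distributions(base_config)
        draws = sample_psa(dists, 5, seed=2)
        draws.loc[2, f"arms.{FIVE_GRASS}.disc_y1"] = 1.7  # invalid probability
        with pytest.warns(UserWarning, match="draw 2 failed"):
            psa = run_psa(base_config, draws, arms=(FIVE_GRASS,), seed=2)
        assert psa.n_failures == 1
        assert psa.n_draws == 5
        assert np.isnan(psa.costs[FIVE_GRASS][2])


@pytest.fixture(scope="module")
def small_psa(base_config):
    draws = sample_psa(build_distributions(base_config), 300, seed=17)
    return run_psa(base_config, draws, seed=17)


class TestCEAC:
    def test_probabilities_sum_to_one(self, small_psa):
        curve = ceac(small_psa, [0, 10000, 20000, 50000])
        np.testing.assert_allclose(curve.probabilities.sum(axis=1), 1.0, atol=1e-12)
        assert ((curve.probabilities >= 0) & (curve.probabilities <= 1)).all().all()

    def test_zero_wtp_prefers_cheapest(self, small_psa):
        """At lambda = 0 the NMB ranking is the (negative) cost ranking."""
        curve = ceac(small_psa, [0.0])
        cheapest = small_psa.costs.idxmin(axis=1)
        for arm in small_psa.costs.columns:
            assert curve.probabilities[arm].iloc[0] == pytest.approx(
                (cheapest == arm).mean(), abs=1e-12
            )

    def test_two_arm_monotone_when_effect_one_signed(self, small_psa):
        """5-grass vs symptomatic: effect draws are essentially one-signed,
        so the pairwise acceptability curve is monotone in lambda."""
        inc = small_psa.incremental(FIVE_GRASS, SYMPTOMATIC)
        assert (inc["delta_qaly"] > 0).mean() > 0.99
        grid = list(range(0, 60001, 5000))
        curve = ceac(small_psa, grid, arms=(FIVE_GRASS, SYMPTOMATIC))
        p = curve.probabilities[FIVE_GRASS].to_numpy()
        assert np.all(np.diff(p) >= -1.0 / small_psa.n_draws)

    def test_summary_reports_percentiles_and_ne_share(self, small_psa):
        s = psa_summary(small_psa)
        assert s["delta_qaly_ci95"][0] < s["delta_qaly_mean"] < s["delta_qaly_ci95"][1]
        assert 0 <= s["p_ne_quadrant"] <= 1


class TestDSA:
    def test_zero_se_parameter_has_zero_range(self, base_config):
        dists = [ParameterDistribution("costs.c_injection", "gamma", 5.11, 0.0)]
        entries = univariate_dsa(base_config, distributions=dists)
        assert entries[0].qaly_range == 0.0
        assert entries[0].cost_range == 0.0

    def test_tornado_rankings_match_published_drivers(self, base_config):
        """Efficacy tops the QALY tornado; season length tops the cost
        tornado."""
        by_qaly = univariate_dsa(base_config, sort_by="qaly")
        assert by_qaly[0].parameter.startswith(EFFICACY_PREFIX)
        by_cost = univariate_dsa(base_config, sort_by="cost")
        assert by_cost[0].parameter == "utility.season_months"

    def test_base_case_between_bounds_for_monotone_parameter(
        self, base_config, base_results
    ):
        dists = [
            d
            for d in build_distributions(base_config)
            if d.path == EFFICACY_PREFIX + FIVE_GRASS
        ]
        entry = univariate_dsa(base_config, distributions=dists)[0]
        base_dq = (
            base_results[FIVE_GRASS].qalys_discounted
            - base_results[ALLERGOID].qalys_discounted
        )
        lo, hi = sorted((entry.dqaly_low, entry.dqaly_high))
        assert lo <= base_dq <= hi
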