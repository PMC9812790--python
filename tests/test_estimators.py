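import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import statsmodels.api as sm

from mrkit.estimators import (
    Z_975,
    cochran_q,
    egger,
    funnel_data,
    heterogeneity_from_q,
    ivw,
    leave_one_out,
    pval_from_or_ci,
    to_odds_scale,
    wald_ratios,
    weighted_median,
    weighted_median_point,
)
from mrkit.instruments import harmonize
from mrkit.simulate import SyntheticConfig, simulate_two_sample

import oracles
from conftest import make_harmonized, harmonized_from_sim


class TestWaldRatios:
    def test_first_order_arithmetic(self):
        data = make_harmonized([0.1], [0.05], [0.02])
        theta, se, ids, excluded = wald_ratios(data)
        assert theta[0] == pytest.approx(0.5)
        assert se[0] == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        data = make_harmonized([0.1], [0.0], [0.02])
        theta, se, _, _ = wald_ratios(data)
        assert theta[0] == 0.0 and se[0] == pytest.approx(0.2)

    def test_zero_exposure_effect_excluded(self):
        data = make_harmonized([0.1, 0.0], [0.05, 0.01], [0.02, 0.02])
        theta, se, ids, excluded = wald_ratios(data)
        assert ids == ["rs1"] and excluded == ["rs2"]

    def test_mean_ratio_recovers_simulated_truth(self):
        d = simulate_two_sample(
            SyntheticConfig(j=50, theta_true=0.2, pleiotropy="none", seed=5)
        )
        theta, se, _, _ = wald_ratios(harmonized_from_sim(d))
        mc_se = np.std(theta, ddof=1) / math.sqrt(theta.size)
        assert abs(np.mean(theta) - 0.2) < 3 * mc_se


class TestIVW:
    def test_degenerate_identical_ratios(self):
        data = make_harmonized([0.1, 0.2], [0.05, 0.10], [0.02, 0.02])
        est, het = ivw(data, mode="fixed")
        assert est.beta == pytest.approx(0.5)
        assert het.q == pytest.approx(0.0, abs=1e-24)

    def test_equal_weights_gives_mean_of_ratios(self):
        data = make_harmonized([0.1, 0.1], [0.04, 0.06], [0.02, 0.02])
        est, _ = ivw(data, mode="fixed")
        assert est.beta == pytest.approx((0.4 + 0.6) / 2)

    def test_single_instrument_directs_to_wald(self):
        data = make_harmonized([0.1], [0.05], [0.02])
        with pytest.raises(ValueError, match="wald_ratios"):
            ivw(data)

    def test_mre_se_is_fixed_se_scaled_by_sqrt_phi(self):
        data = make_harmonized([0.1, 0.12, 0.09, 0.11], [0.05, 0.01, 0.03, 0.06],
                               [0.02, 0.03, 0.02, 0.025])
        fixed, het = ivw(data, mode="fixed")
        mre, _ = ivw(data, mode="mre")
        assert mre.beta == fixed.beta
        assert mre.se == pytest.approx(fixed.se * math.sqrt(het.q / het.df))

    def test_floor_phi_restores_conservative_se(self):
        data = make_harmonized([0.1, 0.2], [0.05, 0.10], [0.02, 0.02])
        mre, _ = ivw(data, mode="mre", floor_phi=True)
        fixed, _ = ivw(data, mode="fixed")
        assert mre.se == fixed.se  # phi == 0 floored to 1

    def test_equal_se_reduces_to_ols_through_origin(self, rng):
        bx = rng.normal(0.1, 0.03, size=12)
        by = 0.3 * bx + rng.normal(0, 0.01, size=12)
        data = make_harmonized(bx, by, np.full(12, 0.02))
        est, _ = ivw(data, mode="fixed")
        ols = float(np.sum(bx * by) / np.sum(bx**2))
        assert est.beta == pytest.approx(ols, rel=1e-12)

    def test_matches_brute_force_summation(self, rng):
        for _ in range(5):
            j = int(rng.integers(2, 11))
            bx = rng.normal(0.1, 0.05, size=j)
            by = rng.normal(0.02, 0.02, size=j)
            sy = rng.uniform(0.01, 0.05, size=j)
            data = make_harmonized(bx, by, sy)
            est, het = ivw(data, mode="fixed")
            theta_b, se_b = oracles.ivw_brute(bx, None, by, sy)
            assert est.beta == pytest.approx(theta_b, rel=1e-12)
            assert est.se == pytest.approx(se_b, rel=1e-12)
            assert het.q == pytest.approx(
                oracles.cochran_brute(bx, by, sy, theta_b), rel=1e-12
            )


class TestCochranQ:
    def test_identical_ratios_zero_q(self):
        het = cochran_q([0.5, 0.5, 0.5], [0.1, 0.2, 0.3], 0.5)
        assert het.q == 0.0 and het.i2 == 0.0

    def test_pvalue_matches_numerical_integration(self):
        het = cochran_q([0.1, 0.5, 0.9, 0.3], [0.1, 0.2, 0.3, 0.15], 0.4)
        assert het.pval == pytest.approx(oracles.chi2_sf_quad(het.q, het.df), abs=1e-8)

    def test_i2_definition(self):
        het = heterogeneity_from_q(q=90.0, df=45)
        assert het.i2 == pytest.approx(50.0)
        assert heterogeneity_from_q(q=30.0, df=45).i2 == 0.0


class TestEgger:
    def test_two_snp_exact_fit_rejected(self):
        data = make_harmonized([0.1, 0.2], [0.05, 0.1], [0.02, 0.02])
        with pytest.raises(ValueError, match="3 instruments"):
            egger(data)

    def test_null_pleiotropy_intercept_near_zero(self):
        d = simulate_two_sample(
            SyntheticConfig(j=100, theta_true=0.2, pleiotropy="none", seed=42)
        )
        est = egger(harmonized_from_sim(d))
        assert abs(est.intercept) < 3 * est.intercept_se

    def test_orientation_invariance(self, rng):
        bx = rng.normal(0.1, 0.05, size=8)
        by = rng.normal(0.02, 0.02, size=8)
        sy = rng.uniform(0.01, 0.05, size=8)
        base = egger(make_harmonized(bx, by, sy))
        flipped = egger(make_harmonized(-bx, -by, sy))
        assert flipped.beta == pytest.approx(base.beta, rel=1e-12)
        assert flipped.intercept == pytest.approx(base.intercept, rel=1e-12)

    def test_matches_brute_force_and_statsmodels(self, rng):
        for _ in range(5):
            j = int(rng.integers(4, 11))
            bx = np.abs(rng.normal(0.1, 0.05, size=j))
            by = rng.normal(0.02, 0.02, size=j)
            sy = rng.uniform(0.01, 0.05, size=j)
            est = egger(make_harmonized(bx, by, sy))
            a_b, s_b, sea_b, ses_b, phi_b = oracles.egger_brute_oriented(bx, by, sy)
            assert est.beta == pytest.approx(s_b, rel=1e-12)
            assert est.intercept == pytest.approx(a_b, rel=1e-12)
            assert est.se == pytest.approx(ses_b, rel=1e-12)
            assert est.intercept_se == pytest.approx(sea_b, rel=1e-12)

            wls = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
            assert est.intercept == pytest.approx(wls.params[0], rel=1e-10)
            assert est.beta == pytest.approx(wls.params[1], rel=1e-10)
            if phi_b >= 1:  # statsmodels never floors the scale
                assert est.se == pytest.approx(wls.bse[1], rel=1e-10)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        assert weighted_median_point(np.array([0.1, 0.5, 0.9]), np.ones(3)) == \
            pytest.approx(0.5)

    def test_majority_weight_validity(self):
        # 34 precise instruments at ratio 0.2 dominate 15 imprecise ones at 5.0
        bx = np.ones(49)
        by = np.concatenate([np.full(34, 0.2), np.full(15, 5.0)])
        sy = np.concatenate([np.full(34, 0.01), np.full(15, 0.1)])
        est = weighted_median(make_harmonized(bx, by, sy), n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-6)

    def test_matches_brute_force_scan(self, rng):
        for _ in range(5):
            j = int(rng.integers(3, 11))
            ratios = rng.normal(0.3, 0.2, size=j)
            weights = rng.uniform(0.5, 5.0, size=j)
            mine = weighted_median_point(ratios, weights)
            ref = oracles.weighted_median_brute(list(ratios), list(weights))
            assert mine == pytest.approx(ref, rel=1e-12)

    def test_bootstrap_seed_reproducible(self):
        data = make_harmonized([0.1, 0.12, 0.09], [0.05, 0.05, 0.04],
                               [0.02, 0.03, 0.02])
        a = weighted_median(data, n_boot=200, seed=9)
        b = weighted_median(data, n_boot=200, seed=9)
        assert a == b

    def test_robust_to_thirty_pct_invalid(self):
        from mrkit.simulate import scenario
        d = simulate_two_sample(scenario("thirty_pct_invalid", seed=8))
        est = weighted_median(harmonized_from_sim(d), n_boot=500, seed=8)
        assert abs(est.beta - 0.2) < 3 * est.se

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ratios=st.lists(st.floats(-5, 5), min_size=3, max_size=20),
        seed=st.integers(0, 10),
    )
    def test_estimate_within_ratio_range(self, ratios, seed):
        rng = np.random.default_rng(seed)
        weights = rng.uniform(0.1, 10.0, size=len(ratios))
        est = weighted_median_point(np.array(ratios), weights)
        assert min(ratios) - 1e-12 <= est <= max(ratios) + 1e-12


class TestLeaveOneOut:
    def test_identical_ratios_all_rows_equal(self):
        data = make_harmonized([0.1, 0.2, 0.4], [0.05, 0.1, 0.2],
                               [0.02, 0.02, 0.02])
        loo = leave_one_out(data)
        assert len(loo) == 4
        assert loo["beta"].to_numpy() == pytest.approx(np.full(4, 0.5), rel=1e-12)

    def test_planted_outlier_most_influential(self):
        bx = np.full(10, 0.1)
        by = np.full(10, 0.05)
        by[3] = 0.5  # ratio 5 vs 0.5 elsewhere
        data = make_harmonized(bx, by, np.full(10, 0.02))
        loo = leave_one_out(data)
        full = loo.loc[loo["snp"] == "all", "beta"].item()
        influence = (loo[loo["snp"] != "all"]
                     .assign(d=lambda t: (t["beta"] - full).abs()))
        assert influence.loc[influence["d"].idxmax(), "snp"] == "rs4"

    def test_row_count_is_j_plus_one(self, strong_sim):
        data = harmonized_from_sim(strong_sim)
        assert len(leave_one_out(data)) == data.n_snp + 1


class TestFunnel:
    def test_precision_is_reciprocal_se(self):
        data = make_harmonized([0.1], [0.05], [0.02])  # ratio se = 0.2
        f = funnel_data(data)
        assert f["precision"].iloc[0] == pytest.approx(5.0)

    def test_ivw_is_precision_weighted_mean(self, strong_sim):
        data = harmonized_from_sim(strong_sim)
        f = funnel_data(data)
        est, _ = ivw(data, mode="fixed")
        weighted_mean = np.average(f["theta"], weights=f["precision"] ** 2)
        assert weighted_mean == pytest.approx(est.beta, rel=1e-10)

    def test_one_row_per_instrument(self, strong_sim):
        data = harmonized_from_sim(strong_sim)
        assert len(funnel_data(data)) == data.n_snp


class TestOddsScale:
    def test_null_effect_is_or_one(self):
        data = make_harmonized([0.1, 0.2], [0.0, 0.0], [0.02, 0.02])
        est, _ = ivw(data, mode="fixed")
        assert to_odds_scale(est).or_value == pytest.approx(1.0)

    def test_exp_inverse(self):
        data = make_harmonized([1.0, 1.0], [math.log(0.983)] * 2, [0.02, 0.02])
        est, _ = ivw(data, mode="fixed")
        assert to_odds_scale(est).or_value == pytest.approx(0.983, rel=1e-12)

    def test_pval_from_reported_or_and_ci(self):
        # A null-looking reported result: OR 0.846 (0.345-2.072) should give
        # a two-sided normal p near 0.714.
        assert pval_from_or_ci(0.846, 0.345, 2.072) == pytest.approx(0.714, abs=7e-4)


class TestCoverage:
    def test_mre_ci_covers_truth_at_nominal_rate(self):
        # quick 100-replicate check; the full 500-replicate study runs in the
        # acceptance suite
        hits = 0
        for s in range(100):
            d = simulate_two_sample(
                SyntheticConfig(j=50, theta_true=0.15, pleiotropy="none", seed=s)
            )
            est, _ = ivw(harmonized_from_sim(d), mode="mre")
            hits += est.ci_low <= 0.15 <= est.ci_high
        assert 88 <= hits <= 100
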