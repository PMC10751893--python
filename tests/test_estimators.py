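"""Estimator family: Wald ratios, IVW, MR-Egger, medians, MVMR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivmr.estimators import (
    egger,
    ivw,
    mvmr,
    penalized_weighted_median,
    ratio_estimates,
    simple_median,
    to_odds_ratio,
    weighted_median,
)
from ivmr.harmonize import MultiExposureSet
from ivmr.simulate import ScenarioConfig, simulate_instrument_set

from conftest import (
    make_hset,
    oracle_chi2_1_sf,
    oracle_cov_var_slope,
    oracle_ivw_grid,
    oracle_weighted_median_dense,
    three_snp_set,  # noqa: F401
)


class TestRatio:
    def test_arithmetic(self):
        h = make_hset([0.5], [0.01], [1.0], [0.1])
        b, se = ratio_estimates(h)
        assert b[0] == pytest.approx(2.0)
        assert se[0] == pytest.approx(0.2)

    def test_joint_sign_flip_invariance(self):
        h1 = make_hset([0.5], [0.01], [1.0], [0.1])
        h2 = make_hset([-0.5], [0.01], [-1.0], [0.1])
        assert ratio_estimates(h1)[0][0] == ratio_estimates(h2)[0][0]

    def test_three_snp_fixture_elementwise(self, three_snp_set):
        # desk oracle computed by hand before the implementation:
        # ratios 0.05/0.1, 0.08/0.2, 0.2/0.3; ses 0.01/0.1, 0.02/0.2, 0.03/0.3
        b, se = ratio_estimates(three_snp_set)
        np.testing.assert_allclose(b, [0.5, 0.4, 2.0 / 3.0], rtol=1e-12)
        np.testing.assert_allclose(se, [0.1, 0.1, 0.1], rtol=1e-12)

    def test_zero_gamma_raises_naming_snp(self):
        h = make_hset([0.0, 0.1], [0.01, 0.01], [0.1, 0.1], [0.1, 0.1])
        with pytest.raises(ValueError, match="rs1"):
            ratio_estimates(h)


class TestIVW:
    def test_consensus_ratios_returned_regardless_of_weights(self):
        h = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.03, 0.06, 0.12],
                      [0.01, 0.05, 0.2])
        assert ivw(h).beta_hat == pytest.approx(0.3, rel=1e-12)

    def test_single_snp_collapses_to_ratio(self):
        h = make_hset([0.5], [0.01], [1.0], [0.1])
        est = ivw(h)
        assert est.beta_hat == pytest.approx(2.0)
        assert est.se == pytest.approx(0.2)
        with pytest.raises(ValueError):
            ivw(h, model="mre")

    def test_matches_grid_search_oracle(self, three_snp_set):
        b, _ = ratio_estimates(three_snp_set)
        w = three_snp_set.gamma_hat**2 / three_snp_set.se_y**2
        expected = oracle_ivw_grid(b, w, lo=0.0, hi=1.0)
        assert ivw(three_snp_set).beta_hat == pytest.approx(expected, abs=1e-6)

    def test_equals_zero_intercept_wls_slope(self):
        hset, _ = simulate_instrument_set(ScenarioConfig(n_snps=30, seed=17))
        x, y = hset.gamma_hat, hset.Gamma_hat
        w = 1.0 / hset.se_y**2
        slope = np.sum(w * x * y) / np.sum(w * x * x)
        assert ivw(hset).beta_hat == pytest.approx(slope, rel=1e-12)

    def test_mre_se_never_below_fixed(self):
        hset, _ = simulate_instrument_set(
            ScenarioConfig(n_snps=30, pleiotropy_mode="balanced",
                           pleiotropy_sd=0.1, invalid_fraction=0.5, seed=3)
        )
        assert ivw(hset, "mre").se >= ivw(hset, "fixed").se
        assert ivw(hset, "mre").beta_hat == ivw(hset, "fixed").beta_hat


class TestEgger:
    def test_exact_line_recovered_either_weighting(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_hset(g, [0.01] * 4, 0.1 + 0.5 * g, [0.02] * 4)
        for weighting in ("unweighted", "inverse_variance"):
            slope, intercept = egger(h, weighting=weighting)
            assert slope.beta_hat == pytest.approx(0.5, abs=1e-10)
            assert intercept.intercept_hat == pytest.approx(0.1, abs=1e-10)
            assert slope.se == pytest.approx(0.0, abs=1e-12)

    def test_proportional_effects_zero_intercept(self):
        g = np.array([0.1, 0.25, 0.3])
        h = make_hset(g, [0.01] * 3, 0.4 * g, [0.02] * 3)
        _, intercept = egger(h)
        assert intercept.intercept_hat == pytest.approx(0.0, abs=1e-12)

    def test_unweighted_slope_matches_cov_var_oracle(self):
        rng = np.random.default_rng(5)
        g = rng.uniform(0.05, 0.3, 6)
        G = 0.3 * g + rng.normal(0, 0.02, 6)
        h = make_hset(g, [0.01] * 6, G, [0.02] * 6)
        slope, intercept = egger(h, weighting="unweighted")
        exp_slope, exp_int = oracle_cov_var_slope(g, G)
        assert slope.beta_hat == pytest.approx(exp_slope, abs=1e-10)
        assert intercept.intercept_hat == pytest.approx(exp_int, abs=1e-10)

    def test_too_few_instruments(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(ValueError):
            egger(h)

    def test_invariant_to_allele_recoding_after_orientation(self):
        hset, _ = simulate_instrument_set(ScenarioConfig(n_snps=12, seed=19))
        data = hset.data.copy()
        data.loc[3, ["gamma_hat", "Gamma_hat"]] *= -1
        flipped = type(hset)(data)
        s1, i1 = egger(hset)
        s2, i2 = egger(flipped)
        assert s1.beta_hat == pytest.approx(s2.beta_hat, rel=1e-12)
        assert i1.intercept_hat == pytest.approx(i2.intercept_hat, rel=1e-12)


class TestMedians:
    def test_simple_median_odd(self):
        h = make_hset([1.0, 1.0, 1.0], [0.01] * 3, [1.0, 2.0, 9.0], [0.1] * 3)
        assert simple_median(h, n_boot=10).beta_hat == pytest.approx(2.0)

    def test_simple_median_even(self):
        h = make_hset([1.0] * 4, [0.01] * 4, [1.0, 2.0, 4.0, 9.0], [0.1] * 4)
        assert simple_median(h, n_boot=10).beta_hat == pytest.approx(3.0)

    def test_equal_weights_reduce_weighted_to_simple(self):
        h = make_hset([1.0, 1.0, 1.0], [0.01] * 3, [1.0, 2.0, 9.0], [0.1] * 3)
        wm = weighted_median(h, weights=np.ones(3), n_boot=10)
        assert wm.beta_hat == pytest.approx(2.0)

    def test_dominant_weight_bounds(self):
        h = make_hset([1.0, 1.0], [0.01] * 2, [0.2, 5.0], [0.1] * 2)
        est = weighted_median(h, weights=np.array([0.99, 0.01]), n_boot=10)
        assert 0.2 <= est.beta_hat <= 0.3

    def test_five_snp_fixture_matches_dense_inversion_oracle(self):
        b = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        w = np.array([1.0, 1.0, 2.0, 4.0, 8.0]) / 16.0
        h = make_hset(np.ones(5), [0.01] * 5, b, [0.1] * 5)
        est = weighted_median(h, weights=w, n_boot=10)
        expected = oracle_weighted_median_dense(b, w)
        assert est.beta_hat == pytest.approx(expected, abs=1e-6)

    def test_nonpositive_weight_rejected(self):
        h = make_hset([1.0, 1.0], [0.01] * 2, [0.2, 5.0], [0.1] * 2)
        with pytest.raises(ValueError):
            weighted_median(h, weights=np.array([1.0, 0.0]), n_boot=10)

    def test_bootstrap_se_reproducible(self):
        hset, _ = simulate_instrument_set(ScenarioConfig(n_snps=20, seed=23))
        a = weighted_median(hset, n_boot=200, seed=11)
        b = weighted_median(hset, n_boot=200, seed=11)
        assert a.se == b.se
        assert a.se > 0


class TestPenalizedMedian:
    def test_homogeneous_panel_identical_to_weighted(self):
        g = np.array([0.1, 0.2, 0.4])
        h = make_hset(g, [0.01] * 3, 0.3 * g, [0.01, 0.05, 0.2])
        pw = penalized_weighted_median(h, n_boot=10, seed=1)
        wm = weighted_median(h, n_boot=10, seed=1)
        assert pw.beta_hat == pytest.approx(wm.beta_hat, rel=1e-12)

    def test_penalty_never_increases_weight(self):
        from ivmr.estimators import _ivw_weights, _penalized_weights

        hset, _ = simulate_instrument_set(
            ScenarioConfig(n_snps=30, pleiotropy_mode="balanced",
                           pleiotropy_sd=0.1, invalid_fraction=0.3, seed=29)
        )
        b, _ = ratio_estimates(hset)
        w = _ivw_weights(hset)
        w_star, _ = _penalized_weights(b, w, 20.0, 0.05)
        assert (w_star <= w + 1e-15).all()

    def test_outlier_weight_ratio_equals_twenty_q(self):
        # one planted outlier; its penalized/raw weight ratio must equal
        # 20*q_j with q_j from an independent erfc-based chi-square tail
        from ivmr.estimators import _ivw_weights, _penalized_weights

        rng = np.random.default_rng(31)
        g = rng.uniform(0.1, 0.3, 10)
        G = 0.3 * g
        G[4] += 0.5  # large direct effect
        h = make_hset(g, [0.01] * 10, G, [0.02] * 10)
        b, _ = ratio_estimates(h)
        w = _ivw_weights(h)
        w_star, _ = _penalized_weights(b, w, 20.0, 0.05)
        beta_ivw = float(np.sum(w * b) / np.sum(w))
        Qj4 = w[4] * (b[4] - beta_ivw) ** 2
        q4 = oracle_chi2_1_sf(Qj4)
        assert w_star[4] / w[4] == pytest.approx(min(1.0, 20.0 * q4), rel=1e-9)
        assert w_star[4] < w[4]


class TestMVMR:
    def test_single_exposure_equals_fixed_ivw(self, three_snp_set):
        uni = ivw(three_snp_set)
        mset = MultiExposureSet(
            snp=three_snp_set.snp,
            gamma_hat=three_snp_set.gamma_hat[:, None],
            se_x=three_snp_set.se_x[:, None],
            Gamma_hat=three_snp_set.Gamma_hat,
            se_y=three_snp_set.se_y,
            exposures=["x1"],
        )
        est = mvmr(mset)[0]
        assert est.beta_hat == pytest.approx(uni.beta_hat, rel=1e-12)
        assert est.se == pytest.approx(uni.se, rel=1e-12)

    def test_six_snp_two_exposure_normal_equations_oracle(self):
        rng = np.random.default_rng(37)
        X = rng.uniform(0.05, 0.3, (6, 2))
        beta_true = np.array([0.4, -0.2])
        y = X @ beta_true + rng.normal(0, 0.01, 6)
        se_y = rng.uniform(0.01, 0.05, 6)
        mset = MultiExposureSet(
            snp=np.array([f"rs{i}" for i in range(6)]),
            gamma_hat=X, se_x=np.full((6, 2), 0.01),
            Gamma_hat=y, se_y=se_y, exposures=["x1", "x2"],
        )
        W = np.diag(1.0 / se_y**2)
        expected = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        got = [e.beta_hat for e in mvmr(mset)]
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_more_exposures_than_snps_rejected(self):
        mset = MultiExposureSet(
            snp=np.array(["rs1", "rs2"]),
            gamma_hat=np.ones((2, 2)) + np.eye(2),
            se_x=np.full((2, 2), 0.01),
            Gamma_hat=np.array([0.1, 0.2]),
            se_y=np.array([0.05, 0.05]),
            exposures=["x1", "x2"],
        )
        with pytest.raises(ValueError, match="more instruments than exposures"):
            mvmr(mset)

    def test_rank_deficient_exposure_matrix_rejected(self):
        X = np.column_stack([np.arange(1.0, 6.0), 2 * np.arange(1.0, 6.0)])
        mset = MultiExposureSet(
            snp=np.array([f"rs{i}" for i in range(5)]),
            gamma_hat=X, se_x=np.full((5, 2), 0.01),
            Gamma_hat=np.ones(5), se_y=np.full(5, 0.05),
            exposures=["x1", "x2"],
        )
        with pytest.raises(ValueError, match="rank"):
            mvmr(mset)

    def test_null_second_exposure_leaves_first_estimate_unbiased(self):
        # exposure 2 has no causal effect and instruments independent of
        # exposure 1's: the joint estimate of exposure 1 should agree with
        # its univariable IVW across replicates
        rng = np.random.default_rng(41)
        reps, J = 300, 20
        diff = np.empty(reps)
        uni_se = np.empty(reps)
        for r in range(reps):
            g1 = rng.uniform(0.05, 0.2, J)
            g2 = rng.uniform(0.05, 0.2, J)
            se_y = np.full(J, 0.02)
            y = 0.3 * g1 + 0.0 * g2 + rng.normal(0, 0.02, J)
            w = 1.0 / se_y**2
            mset = MultiExposureSet(
                snp=np.array([f"rs{i}" for i in range(J)]),
                gamma_hat=np.column_stack([g1, g2]),
                se_x=np.full((J, 2), 0.005),
                Gamma_hat=y, se_y=se_y, exposures=["x1", "x2"],
            )
            est1 = mvmr(mset)[0].beta_hat
            uni = np.sum(w * g1 * y) / np.sum(w * g1 * g1)
            diff[r] = est1 - 0.3
            uni_se[r] = np.sum(w * g1 * g1) ** -0.5
        mc_se = diff.std(ddof=1) / np.sqrt(reps)
        assert abs(diff.mean()) < 3 * mc_se


class TestOddsRatio:
    def test_null(self):
        assert to_odds_ratio(0.0, 0.0) == (1.0, 1.0, 1.0)

    def test_log2(self):
        o, lo, hi = to_odds_ratio(np.log(2.0), 0.0)
        assert o == pytest.approx(2.0) and lo == pytest.approx(2.0)

    @given(beta=st.floats(-3, 3), se=st.floats(0, 2))
    @settings(max_examples=50, deadline=None)
    def test_log_symmetry_identity(self, beta, se):
        o, lo, hi = to_odds_ratio(beta, se)
        assert o**2 == pytest.approx(lo * hi, rel=1e-9)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=10, deadline=None)
def test_estimators_invariant_to_snp_order(seed):
    hset, _ = simulate_instrument_set(ScenarioConfig(n_snps=15, seed=seed))
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(15)
    shuffled = type(hset)(hset.data.iloc[perm].reset_index(drop=True))
    assert ivw(shuffled).beta_hat == pytest.approx(ivw(hset).beta_hat, rel=1e-12)
    assert egger(shuffled)[0].beta_hat == pytest.approx(
        egger(hset)[0].beta_hat, rel=1e-9
    )
    assert weighted_median(shuffled, n_boot=2).beta_hat == pytest.approx(
        weighted_median(hset, n_boot=2).beta_hat, rel=1e-12
    )


@given(seed=st.integers(0, 10_000))
@settings(max_examples=10, deadline=None)
def test_ratio_family_invariant_to_allele_recoding(seed):
    hset, _ = simulate_instrument_set(ScenarioConfig(n_snps=12, seed=seed))
    rng = np.random.default_rng(seed + 2)
    sign = rng.choice([-1.0, 1.0], 12)
    data = hset.data.copy()
    data["gamma_hat"] *= sign
    data["Gamma_hat"] *= sign
    recoded = type(hset)(data)
    assert ivw(recoded).beta_hat == pytest.approx(ivw(hset).beta_hat, rel=1e-12)
    assert weighted_median(recoded, n_boot=2).beta_hat == pytest.approx(
        weighted_median(hset, n_boot=2).beta_hat, rel=1e-12
    )
    assert simple_median(recoded, n_boot=2).beta_hat == pytest.approx(
        simple_median(hset, n_boot=2).beta_hat, rel=1e-12
    )
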