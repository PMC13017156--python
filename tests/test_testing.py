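"""Structured decisions, mFDR thresholding, baselines and rate evaluators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from bnsbm import (
    Decision,
    FitOptions,
    LatentTruth,
    ScoreMatrix,
    bh_reject,
    decide,
    ell_value,
    empirical_rates,
    fit,
    lvalue_matrix,
    mfdr_threshold,
    sample_noisysbm,
    scenario_a_params,
    storey_q,
    zscores_to_pvalues,
)
from oracles import bh_stepup, mfdr_threshold_enumerated


class TestMfdrThreshold:
    def test_running_mean_toy_example(self):
        # running means 0.01, 0.015, 0.1767 -> reject the two smallest
        lv = np.array([0.01, 0.02, 0.50])
        tau, reject = mfdr_threshold(lv, 0.1)
        assert tau == pytest.approx(0.02)
        np.testing.assert_array_equal(reject, [True, True, False])

    def test_alpha_one_rejects_everything(self, rng):
        lv = rng.uniform(size=20)
        tau, reject = mfdr_threshold(lv, 1.0)
        assert reject.all()

    def test_no_qualifying_threshold(self):
        tau, reject = mfdr_threshold(np.array([0.5, 0.6]), 0.1)
        assert tau == -np.inf and not reject.any()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mfdr_threshold(np.array([]), 0.1)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1), st.floats(0.02, 0.5))
    def test_matches_enumeration_and_controls_plugin_mfdr(self, seed, alpha):
        lv = np.random.default_rng(seed).uniform(size=25)
        tau, reject = mfdr_threshold(lv, alpha)
        assert tau == pytest.approx(mfdr_threshold_enumerated(lv, alpha))
        if reject.any():
            assert lv[reject].mean() <= alpha + 1e-12

    def test_ties_at_tau_all_rejected(self):
        lv = np.array([0.01, 0.02, 0.02, 0.9])
        tau, reject = mfdr_threshold(lv, 0.05)
        assert reject.sum() == 3


@pytest.fixture(scope="module")
def scenario_fit():
    X, truth = sample_noisysbm(60, 80, scenario_a_params(), seed=4)
    res = fit(X, FitOptions(B1=3, B2=3, n_restarts=3, seed=0))
    return X, truth, res


class TestLvalueMatrixAndDecide:

    def test_matrix_matches_entrywise_calls(self, scenario_fit):
        X, _, res = scenario_fit
        L = lvalue_matrix(X, res)
        for i in (0, 17, 59):
            for j in (0, 33, 79):
                expected = ell_value(
                    X.values[i, j], res.Z1_hat[i], res.Z2_hat[j], res.theta_hat
                )
                assert L[i, j] == pytest.approx(expected, abs=1e-12)

    def test_reject_is_threshold_of_lvalues(self, scenario_fit):
        X, _, res = scenario_fit
        dec = decide(X, res, alpha=0.1)
        np.testing.assert_array_equal(dec.reject, (dec.lvalues <= dec.tau).astype(int))
        if dec.n_rejected:
            assert dec.mfdr_hat <= 0.1

    def test_rejections_nested_in_alpha(self, scenario_fit):
        X, _, res = scenario_fit
        d05 = decide(X, res, alpha=0.05)
        d10 = decide(X, res, alpha=0.10)
        assert d05.n_rejected <= d10.n_rejected
        assert not np.any((d05.reject == 1) & (d10.reject == 0))

    def test_floor_pi_block_has_lvalues_near_one(self, rng):
        from bnsbm import BlockModelParams, VariationalState, gaussian
        from bnsbm.vem import FitResult

        theta = BlockModelParams(
            alpha1=[1.0], alpha2=[1.0], Pi=[[0.0]],  # clipped to the floor
            nu0=gaussian(0, 1, n_free_params=0), nu=[[gaussian(2, 1)]],
        )
        x = rng.normal(size=(5, 5))
        res = FitResult(
            theta, VariationalState(np.ones((5, 1)), np.ones((5, 1))),
            np.zeros(5, int), np.zeros(5, int), np.array([0.0]), True,
        )
        L = lvalue_matrix(ScoreMatrix(x), res)
        assert np.all(L > 0.999)

    def test_all_null_data_yields_no_discoveries(self):
        """Empirical FDR under the global null stays at zero: with every
        entry null the fitted alternative collapses and nothing is rejected."""
        rng = np.random.default_rng(123)
        fdps = []
        for rep in range(20):
            x = rng.normal(size=(40, 50))
            X = ScoreMatrix(x)
            res = fit(X, FitOptions(B1=1, B2=1, n_restarts=1, seed=rep, max_outer_iter=40))
            dec = decide(X, res, alpha=0.05)
            truth = LatentTruth(
                A=np.zeros((40, 50), int), Z1=np.zeros(40, int), Z2=np.zeros(50, int)
            )
            fdps.append(empirical_rates(dec, truth).fdp)
        assert np.mean(fdps) <= 0.05


class TestEmpiricalRates:
    def test_perfect_decision(self):
        A = np.array([[1, 0], [0, 1]])
        truth = LatentTruth(A=A, Z1=[0, 0], Z2=[0, 0])
        dec = Decision(lvalues=1 - A.astype(float), tau=0.5, reject=A.copy(),
                       mfdr_hat=0.0, alpha=0.1)
        r = empirical_rates(dec, truth)
        assert r.fdp == 0.0 and r.tdp == 1.0

    def test_reject_all_half_null(self):
        A = np.array([[1, 1], [0, 0]])
        truth = LatentTruth(A=A, Z1=[0, 0], Z2=[0, 0])
        dec = Decision(lvalues=np.zeros((2, 2)), tau=1.0, reject=np.ones((2, 2), int),
                       mfdr_hat=0.5, alpha=0.5)
        assert empirical_rates(dec, truth).fdp == 0.5

    def test_no_rejections_guarded_denominator(self):
        truth = LatentTruth(A=np.ones((2, 2), int), Z1=[0, 0], Z2=[0, 0])
        dec = Decision(lvalues=np.ones((2, 2)), tau=-np.inf,
                       reject=np.zeros((2, 2), int), mfdr_hat=0.0, alpha=0.1)
        r = empirical_rates(dec, truth)
        assert r.fdp == 0.0 and r.tdp == 0.0

    def test_no_true_edges_tdp_is_none(self):
        truth = LatentTruth(A=np.zeros((2, 2), int), Z1=[0, 0], Z2=[0, 0])
        dec = Decision(lvalues=np.ones((2, 2)), tau=-np.inf,
                       reject=np.zeros((2, 2), int), mfdr_hat=0.0, alpha=0.1)
        assert empirical_rates(dec, truth).tdp is None

    def test_shape_mismatch_raises(self):
        truth = LatentTruth(A=np.zeros((2, 3), int), Z1=[0, 0], Z2=[0, 0, 0])
        dec = Decision(lvalues=np.ones((2, 2)), tau=0.0, reject=np.zeros((2, 2), int),
                       mfdr_hat=0.0, alpha=0.1)
        with pytest.raises(ValueError):
            empirical_rates(dec, truth)


class TestBaselines:
    def test_bh_single_small_pvalue(self):
        assert bh_reject(np.array([0.01]), 0.05).sum() == 1

    def test_bh_toy_example(self):
        # 0.01 <= 0.0125 and 0.02 <= 0.025 pass; 0.9 fails
        p = np.array([0.01, 0.02, 0.9, 0.9])
        np.testing.assert_array_equal(bh_reject(p, 0.05), [1, 1, 0, 0])

    def test_bh_all_ones_rejects_none(self):
        assert bh_reject(np.ones(5), 0.05).sum() == 0

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 0.3))
    def test_bh_matches_stepup_enumeration(self, seed, alpha):
        p = np.random.default_rng(seed).uniform(size=30)
        np.testing.assert_array_equal(bh_reject(p, alpha), bh_stepup(p, alpha))

    def test_storey_pi0_hand_count(self):
        p = np.array([0.1, 0.6, 0.7, 0.8])
        # pi0 = min(1, 3 / (0.5 * 4)) = 1 -> q equals BH-adjusted values
        q = storey_q(p, lam=0.5)
        assert q[0] == pytest.approx(min(1.0, 4 * 0.1 / 1))

    def test_storey_uniform_pi0_near_one(self, rng):
        p = rng.uniform(size=5000)
        q = storey_q(p)
        assert q.max() <= 1.0
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_zscores_to_pvalues_two_sided(self):
        z = np.array([0.0, 1.959964])
        p = zscores_to_pvalues(z)
        assert p[0] == pytest.approx(1.0)
        assert p[1] == pytest.approx(0.05, abs=1e-6)


class TestOracleCalibration:
    def test_oracle_lvalue_mfdr_near_nominal(self):
        """With the true parameters and memberships plugged in, thresholding
        the exact l-values at alpha = 0.1 keeps the marginal FDR (ratio of
        summed false rejections to summed rejections over 100 modular
        replicates) within +-0.04 of 0.1, or below."""
        theta = scenario_a_params()
        n_false = n_rej = 0
        for rep in range(100):
            X, truth = sample_noisysbm(150, 200, theta, seed=1000 + rep)
            L = np.empty(X.shape)
            for q in range(3):
                rows = truth.Z1 == q
                for l in range(3):
                    cols = truth.Z2 == l
                    L[np.ix_(rows, cols)] = ell_value(
                        X.values[np.ix_(rows, cols)], q, l, theta
                    )
            _, reject = mfdr_threshold(L, 0.1)
            n_rej += int(reject.sum())
            n_false += int(((1 - truth.A) * reject).sum())
        mfdr = n_false / max(n_rej, 1)
        assert mfdr <= 0.14


class TestStructuredVsBaselinePower:
    def test_structured_tdr_dominates_bh_on_modular_data(self):
        """Block pooling lifts the true discovery rate above BH at matched
        nominal levels on modular data (a small-replicate check of the
        simulation-study ordering)."""
        tdr_s, tdr_b, fdps = [], [], []
        for rep in range(5):
            X, truth = sample_noisysbm(150, 200, scenario_a_params(), seed=100 + rep)
            res = fit(X, FitOptions(B1=3, B2=3, n_restarts=3, seed=rep))
            for alpha in (0.05, 0.1):
                dec = decide(X, res, alpha)
                r = empirical_rates(dec, truth)
                bh = bh_reject(zscores_to_pvalues(X.values), alpha)
                rb = empirical_rates(
                    Decision(dec.lvalues, dec.tau, bh, 0.0, alpha), truth
                )
                tdr_s.append(r.tdp)
                tdr_b.append(rb.tdp)
                if alpha == 0.1:
                    fdps.append(r.fdp)
        assert np.mean(tdr_s) > np.mean(tdr_b)
        assert np.mean(fdps) <= 0.15
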