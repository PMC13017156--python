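"""Variational EM: initialization, E/M steps and the outer loop."""

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

from bnsbm import (
    FitOptions,
    ScoreMatrix,
    VariationalState,
    e_step,
    elbo,
    ell_value,
    fit,
    initialize,
    m_step,
    sample_noisysbm,
    scenario_a_params,
)
from bnsbm.model import responsibility_matrix
from conftest import random_theta
from oracles import naive_m_step, pooled_mixture_em


class TestInitialize:
    def test_separable_row_groups_recovered(self, rng):
        x = np.vstack([rng.normal(5, 0.1, size=(4, 6)), rng.normal(-5, 0.1, size=(4, 6))])
        theta, state = initialize(ScoreMatrix(x), FitOptions(B1=2, B2=1), seed=0)
        labels = state.beta1.argmax(axis=1)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_all_zero_scores_give_floor_pi(self):
        # p-value of x = 0 under N(0,1) is 1 -> rough rho is identically 0
        X = ScoreMatrix(np.zeros((6, 6)) + 1e-12 * np.arange(36).reshape(6, 6))
        theta, _ = initialize(X, FitOptions(B1=1, B2=1), seed=0, refine=False)
        assert theta.Pi[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_pi_matches_tabulation_oracle(self):
        """The raw threshold-moment stage: Pi equals an independent
        group-by average of the p<0.5 indicator."""
        X, truth = sample_noisysbm(40, 50, scenario_a_params(), seed=7)
        opts = FitOptions(B1=3, B2=3)
        theta, state = initialize(X, opts, seed=3, refine=False)
        labels1 = state.beta1.argmax(axis=1)
        labels2 = state.beta2.argmax(axis=1)
        rough = (2.0 * norm.sf(np.abs(X.values)) < 0.5).astype(float)
        for q in range(3):
            for l in range(3):
                block = rough[np.ix_(labels1 == q, labels2 == l)]
                if block.size:
                    assert theta.Pi[q, l] == pytest.approx(block.mean(), abs=1e-9)

    def test_too_many_clusters_rejected(self, rng):
        X = ScoreMatrix(rng.normal(size=(3, 3)))
        with pytest.raises(ValueError):
            initialize(X, FitOptions(B1=5, B2=1), seed=0)


class TestEStep:
    def test_single_block_is_identity(self, rng):
        theta = random_theta(rng, 1, 1)
        X = ScoreMatrix(rng.normal(size=(4, 5)))
        state = VariationalState(np.ones((4, 1)), np.ones((5, 1)))
        out = e_step(X, theta, state)
        np.testing.assert_allclose(out.beta1, 1.0)
        np.testing.assert_allclose(out.beta2, 1.0)

    def test_symmetric_blocks_fix_uniform_state(self, rng):
        from bnsbm import BlockModelParams, gaussian

        theta = BlockModelParams(
            alpha1=[0.5, 0.5], alpha2=[0.5, 0.5], Pi=[[0.3, 0.3], [0.3, 0.3]],
            nu0=gaussian(0, 1, n_free_params=0),
            nu=[[gaussian(2, 1), gaussian(2, 1)], [gaussian(2, 1), gaussian(2, 1)]],
        )
        X = ScoreMatrix(rng.normal(size=(4, 4)))
        state = VariationalState(np.full((4, 2), 0.5), np.full((4, 2), 0.5))
        out = e_step(X, theta, state)
        np.testing.assert_allclose(out.beta1, 0.5, atol=1e-12)
        np.testing.assert_allclose(out.beta2, 0.5, atol=1e-12)

    def test_improves_elbo_and_matches_grid_search(self, rng):
        """One sweep must not decrease the ELBO, and the row update must beat
        every candidate membership row on a fine simplex grid."""
        theta = random_theta(rng, 2, 2)
        X = ScoreMatrix(rng.normal(size=(3, 3)))
        state = VariationalState(
            rng.dirichlet(np.ones(2), size=3), rng.dirichlet(np.ones(2), size=3)
        )
        before = elbo(X, theta, state)
        out = e_step(X, theta, state, inner_iter=5)
        after = elbo(X, theta, out)
        assert after >= before - 1e-9
        # coordinate-wise optimality of each row of beta1 given beta2
        for i in range(3):
            base = elbo(X, theta, out)
            for p in np.linspace(0.001, 0.999, 101):
                b1 = out.beta1.copy()
                b1[i] = [p, 1 - p]
                trial = elbo(X, theta, VariationalState(b1, out.beta2))
                assert trial <= base + 1e-8


class TestMStep:
    def test_one_hot_beta_full_rho_gives_block_means(self, rng):
        x = rng.normal(2.0, 1.0, size=(6, 6))
        X = ScoreMatrix(x)
        theta = random_theta(rng, 2, 2)
        b1 = np.eye(2)[[0, 0, 0, 1, 1, 1]]
        b2 = np.eye(2)[[0, 0, 1, 1, 1, 1]]
        R = np.ones((2, 2, 6, 6))
        new = m_step(X, theta, VariationalState(b1, b2), _R=R)
        assert new.nu[0][0].mean == pytest.approx(x[:3, :2].mean(), abs=1e-10)
        assert new.nu[1][1].mean == pytest.approx(x[3:, 2:].mean(), abs=1e-10)
        np.testing.assert_allclose(new.alpha1.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(new.alpha2.sum(), 1.0, atol=1e-12)

    def test_matches_naive_triple_loop(self, rng):
        x = rng.normal(size=(4, 5))
        X = ScoreMatrix(x)
        theta = random_theta(rng, 2, 3)
        b1 = rng.dirichlet(np.ones(2), size=4)
        b2 = rng.dirichlet(np.ones(3), size=5)
        R = responsibility_matrix(X, theta)
        new = m_step(X, theta, VariationalState(b1, b2), fix_null=False)
        a1, a2, Pi, mu, var, s0 = naive_m_step(x, b1, b2, R)
        np.testing.assert_allclose(new.alpha1, a1, atol=1e-12)
        np.testing.assert_allclose(new.alpha2, a2, atol=1e-12)
        np.testing.assert_allclose(new.Pi, Pi, atol=1e-10)
        np.testing.assert_allclose(new.alt_means, mu, atol=1e-10)
        np.testing.assert_allclose(new.alt_vars, var, atol=1e-10)
        assert new.nu0.variance == pytest.approx(s0, abs=1e-10)

    def test_empty_block_parameters_frozen(self, rng, caplog):
        x = rng.normal(size=(4, 4))
        X = ScoreMatrix(x)
        theta = random_theta(rng, 2, 2)
        b1 = np.zeros((4, 2))
        b1[:, 0] = 1.0  # block 2 on rows has zero weight
        b2 = rng.dirichlet(np.ones(2), size=4)
        import logging

        with caplog.at_level(logging.WARNING, logger="bnsbm.vem"):
            new = m_step(X, theta, VariationalState(b1, b2))
        assert "negligible weight" in caplog.text
        assert new.nu[1][0].mean == theta.nu[1][0].mean
        assert new.nu[1][1].mean == theta.nu[1][1].mean


class TestFit:
    def test_single_block_equals_pooled_mixture_em(self, rng):
        """B1 = B2 = 1 reduces to the classical two-group mixture fit."""
        x = np.where(rng.random((30, 40)) < 0.3, rng.normal(2.5, 1.0, (30, 40)),
                     rng.normal(0, 1.0, (30, 40)))
        X = ScoreMatrix(x)
        res = fit(X, FitOptions(B1=1, B2=1, n_restarts=1, seed=0,
                                max_outer_iter=500, elbo_rel_tol=1e-10))
        pi_o, mu_o, v_o = pooled_mixture_em(
            x, 1.0, res.theta_hat.Pi[0, 0], res.theta_hat.alt_means[0, 0],
            res.theta_hat.alt_vars[0, 0],
        )
        assert res.theta_hat.Pi[0, 0] == pytest.approx(pi_o, abs=1e-4)
        assert res.theta_hat.alt_means[0, 0] == pytest.approx(mu_o, abs=1e-4)
        # l-values agree with the direct one-dimensional mixture
        for xv in (-1.0, 0.5, 2.0, 3.5):
            direct = ((1 - pi_o) * norm.pdf(xv, 0, 1)) / (
                pi_o * norm.pdf(xv, mu_o, np.sqrt(v_o)) + (1 - pi_o) * norm.pdf(xv, 0, 1)
            )
            assert ell_value(xv, 0, 0, res.theta_hat) == pytest.approx(direct, abs=1e-3)

    def test_elbo_trace_nondecreasing(self):
        X, _ = sample_noisysbm(40, 50, scenario_a_params(), seed=11)
        res = fit(X, FitOptions(B1=3, B2=3, n_restarts=2, seed=1))
        assert np.all(np.diff(res.elbo_trace) >= -1e-8)

    def test_scenario_a_membership_recovery(self):
        X, truth = sample_noisysbm(150, 200, scenario_a_params(), seed=5)
        res = fit(X, FitOptions(B1=3, B2=3, n_restarts=5, seed=0))
        assert adjusted_rand_score(truth.Z1, res.Z1_hat) >= 0.9
        assert adjusted_rand_score(truth.Z2, res.Z2_hat) >= 0.9

    def test_row_permutation_equivariance(self, rng):
        from bnsbm import BlockModelParams, gaussian

        strong = BlockModelParams(
            alpha1=[0.65, 0.35], alpha2=[0.6, 0.4], Pi=[[0.9, 0.05], [0.05, 0.9]],
            nu0=gaussian(0, 1, n_free_params=0),
            nu=[[gaussian(4, 1), gaussian(-4, 1)], [gaussian(-4, 1), gaussian(4, 1)]],
        )
        X, _ = sample_noisysbm(30, 40, strong, seed=3)
        perm = np.random.default_rng(0).permutation(30)
        Xp = ScoreMatrix(X.values[perm], [X.row_ids[i] for i in perm], X.col_ids)
        res = fit(X, FitOptions(B1=2, B2=2, n_restarts=3, seed=2))
        resp = fit(Xp, FitOptions(B1=2, B2=2, n_restarts=3, seed=2))
        # canonical labels make the estimates comparable directly
        np.testing.assert_allclose(res.theta_hat.Pi, resp.theta_hat.Pi, atol=5e-2)
        assert adjusted_rand_score(res.Z1_hat[perm], resp.Z1_hat) == pytest.approx(1.0)

    def test_hard_memberships_follow_beta(self):
        X, _ = sample_noisysbm(30, 30, scenario_a_params(), seed=9)
        res = fit(X, FitOptions(B1=2, B2=2, n_restarts=2, seed=0))
        np.testing.assert_array_equal(res.Z1_hat, res.state.beta1.argmax(axis=1))
        np.testing.assert_array_equal(res.Z2_hat, res.state.beta2.argmax(axis=1))


class TestElboMonotonicityBroad:
    def test_traces_nondecreasing_on_many_random_instances(self, rng):
        """Non-decreasing ELBO traces across seeded instances of varying size
        (a quick unit-level check; the broad 200-instance sweep lives in the
        end-to-end suite)."""
        bad = 0
        for k in range(50):
            n1 = int(rng.integers(5, 26))
            n2 = int(rng.integers(5, 26))
            B1 = int(rng.integers(1, 4))
            B2 = int(rng.integers(1, 4))
            theta = random_theta(rng, max(B1, 1), max(B2, 1))
            X, _ = sample_noisysbm(n1, n2, theta, seed=k)
            res = fit(
                X,
                FitOptions(B1=min(B1, n1), B2=min(B2, n2), n_restarts=1, seed=k,
                           max_outer_iter=30),
            )
            if not np.all(np.diff(res.elbo_trace) >= -1e-8):
                bad += 1
        assert bad == 0
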