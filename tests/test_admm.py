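import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from adlasso import (
    ADMMState,
    FitConfig,
    QuadraticCache,
    admm_fit,
    armijo_line_search,
    check_convergence,
    kkt_residual,
    lambda_max,
    penalized_objective,
    prox_quadratic,
    soft_threshold,
)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "v,kappa,expected",
        [(2.0, 1.0, 1.0), (-2.0, 1.0, -1.0), (0.3, 0.5, 0.0), (0.0, 0.0, 0.0)],
    )
    def test_scalar_cases(self, v, kappa, expected):
        assert soft_threshold(np.array([v]), kappa)[0] == pytest.approx(expected)

    def test_kappa_zero_is_identity(self, rng):
        v = rng.normal(size=20)
        np.testing.assert_array_equal(soft_threshold(v, 0.0), v)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)

    @given(
        hnp.arrays(np.float64, 10, elements=st.floats(-100, 100)),
        st.floats(0, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_shrinkage_properties(self, v, kappa):
        s = soft_threshold(v, kappa)
        assert np.all(np.abs(s) <= np.abs(v) + 1e-12)
        assert np.all(s * v >= 0)  # never flips sign
        dead = np.abs(v) <= kappa
        assert np.all(s[dead] == 0)
        live = ~dead
        np.testing.assert_allclose(np.abs(s[live]), np.abs(v[live]) - kappa, atol=1e-12)

    def test_per_coordinate_kappa(self):
        v = np.array([3.0, 3.0, -3.0])
        kappa = np.array([1.0, 2.0, 0.5])
        np.testing.assert_allclose(soft_threshold(v, kappa), [2.0, 1.0, -2.5])


class TestQuadraticCache:
    def test_reconstruction_invariant(self, rng):
        X = rng.normal(size=(15, 40))
        cache = QuadraticCache(X, rng.normal(size=15))
        gram = X @ X.T
        recon = (cache.Q * cache.evals) @ cache.Q.T
        assert np.linalg.norm(recon - gram) / np.linalg.norm(gram) <= 1e-8


class TestProxQuadratic:
    def test_zero_fixed_point(self):
        cache = QuadraticCache(np.eye(3), np.zeros(3))
        np.testing.assert_allclose(prox_quadratic(np.zeros(3), 1.0, cache), 0.0)

    def test_identity_closed_form(self):
        # X = I, y = (3,0,0), v = 0, rho = 1: (y + v/rho)/(1 + 1/rho) = (1.5,0,0)
        cache = QuadraticCache(np.eye(3), np.array([3.0, 0.0, 0.0]))
        np.testing.assert_allclose(
            prox_quadratic(np.zeros(3), 1.0, cache), [1.5, 0.0, 0.0], atol=1e-10
        )

    def test_agrees_with_dense_solve(self, rng):
        n, q = 20, 60
        X = rng.normal(size=(n, q))
        y = rng.normal(size=n)
        v = rng.normal(size=q)
        rho = 0.37
        cache = QuadraticCache(X, y)
        got = prox_quadratic(v, rho, cache)
        # oracle: direct dense solve of the q x q system
        c = 1.0 / rho
        expected = np.linalg.solve(X.T @ X + c * np.eye(q), X.T @ y + c * v)
        assert np.linalg.norm(got - expected) / np.linalg.norm(expected) < 1e-8

    def test_rho_must_be_positive(self):
        cache = QuadraticCache(np.eye(2), np.zeros(2))
        with pytest.raises(ValueError):
            prox_quadratic(np.zeros(2), 0.0, cache)


class TestArmijoLineSearch:
    def test_orthonormal_design_accepts_rho_one(self, rng):
        # Lipschitz constant of grad f is 1 -> rho=1 passes at the first trial
        X = np.linalg.qr(rng.normal(size=(8, 8)))[0]
        y = rng.normal(size=8)
        beta = rng.normal(size=8)
        grad = X.T @ (X @ beta - y)
        rho = armijo_line_search(
            beta, lambda r: beta - r * grad, X, y, FitConfig()
        )
        assert rho == 1.0

    def test_stationary_point_returns_rho0(self, rng):
        X = np.eye(4)
        y = np.array([1.0, -2.0, 0.5, 3.0])
        beta = y.copy()  # gradient is exactly zero; candidate z = beta
        cfg = FitConfig(rho0=0.7)
        rho = armijo_line_search(beta, lambda r: beta, X, y, cfg)
        assert rho == 0.7

    def test_matches_explicit_inequality_oracle(self, rng):
        # scale X so the largest eigenvalue of X'X is 16
        X = rng.normal(size=(12, 12))
        X *= 4.0 / np.sqrt(np.linalg.eigvalsh(X.T @ X).max())
        y = rng.normal(size=12)
        beta = rng.normal(size=12)
        grad = X.T @ (X @ beta - y)
        f = lambda b: 0.5 * np.sum((X @ b - y) ** 2)
        cand = lambda r: beta - r * grad
        accepted = armijo_line_search(beta, cand, X, y, FitConfig())
        # oracle: walk the halving sequence and evaluate both sides directly
        rho = 1.0
        while True:
            z = cand(rho)
            lhs = f(z)
            rhs = f(beta) + grad @ (z - beta) + np.sum((z - beta) ** 2) / (2 * rho)
            if lhs <= rhs + 1e-12 * (1 + abs(f(beta))):
                break
            rho *= 0.5
        assert accepted == rho

    def test_divergence_reported(self):
        X = np.eye(2)
        y = np.zeros(2)
        beta = np.ones(2)
        # non-finite candidates can never satisfy the inequality -> floor hit
        bad = lambda r: beta * np.nan
        with pytest.raises(FloatingPointError):
            armijo_line_search(beta, bad, X, y, FitConfig())


class TestCheckConvergence:
    def _state(self, beta, theta, u):
        return ADMMState(
            beta=np.asarray(beta, float),
            theta=np.asarray(theta, float),
            u=np.asarray(u, float),
            rho=1.0,
        )

    def test_exact_agreement(self):
        s = self._state([1.0, 2.0], [1.0, 2.0], [0.0, 5.0])
        assert check_convergence(s, 1e-12)

    def test_large_residual_fails(self):
        s = self._state([1.0, 0.0], [0.0, 0.0], [0.0, 0.0])
        assert not check_convergence(s, 1e-4)

    def test_dual_scaling(self):
        # ||beta-theta||inf = 2e-4 <= 1e-4 * (1 + 1) with ||u||inf = 1
        s = self._state([2e-4, 0.0], [0.0, 0.0], [1.0, 0.0])
        assert check_convergence(s, 1e-4)


class TestAdmmFit:
    def test_small_lambda_recovers_least_squares(self, rng):
        X = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        y = rng.normal(size=6)
        ls = np.linalg.solve(X, y)
        state, diag = admm_fit(X, y, 1e-10, config=FitConfig(eps_admm=1e-8))
        assert diag.converged
        np.testing.assert_allclose(state.theta, ls, atol=1e-4)

    def test_orthogonal_design_closed_form(self):
        y = np.array([3.0, -2.0, 0.5, 0.0])
        state, diag = admm_fit(np.eye(4), y, 1.0, config=FitConfig(eps_admm=1e-8))
        np.testing.assert_allclose(state.theta, [2.0, -1.0, 0.0, 0.0], atol=1e-6)

    def test_objective_matches_cd_oracle(self, rng):
        from sklearn.linear_model import Lasso

        n, q = 30, 10
        X = rng.normal(size=(n, q))
        y = rng.normal(size=n)
        lam = 0.5 * lambda_max(X, y)
        state, diag = admm_fit(X, y, lam, config=FitConfig(eps_admm=1e-6))
        oracle = Lasso(alpha=lam / n, fit_intercept=False, tol=1e-12, max_iter=100000).fit(X, y)
        obj_oracle = penalized_objective(X, y, oracle.coef_, lam)
        assert abs(diag.objective - obj_oracle) / obj_oracle < 1e-4

    def test_kkt_certificate(self, rng):
        n, q = 25, 40
        X = rng.normal(size=(n, q))
        y = rng.normal(size=n)
        lam = 0.3 * lambda_max(X, y)
        state, diag = admm_fit(X, y, lam, config=FitConfig(eps_admm=1e-6))
        assert diag.converged
        assert kkt_residual(X, y, state.theta, lam) < 1e-3

    def test_theta_zero_at_lambda_max(self, rng):
        X = rng.normal(size=(20, 50))
        y = rng.normal(size=20)
        lam = lambda_max(X, y) * 1.001
        state, diag = admm_fit(X, y, lam, config=FitConfig(eps_admm=1e-6))
        np.testing.assert_array_equal(state.theta, 0.0)

    def test_warm_start_invariance(self, rng):
        n, q = 40, 30
        X = rng.normal(size=(n, q))
        y = rng.normal(size=n)
        lam = 0.4 * lambda_max(X, y)
        cfg = FitConfig(eps_admm=1e-8)
        cold, dc = admm_fit(X, y, lam, config=cfg)
        other, _ = admm_fit(X, y, 2 * lam, config=cfg)
        warm, dw = admm_fit(X, y, lam, config=cfg, warm=(other.beta, other.theta))
        assert abs(dc.objective - dw.objective) / abs(dc.objective) < 1e-6

    def test_unit_weights_equal_gamma_zero(self, rng):
        from adlasso import marginal_weights

        X = rng.normal(size=(20, 15))
        y = rng.normal(size=20)
        lam = 0.5 * lambda_max(X, y)
        cfg = FitConfig(eps_admm=1e-8)
        s1, _ = admm_fit(X, y, lam, weights=np.ones(15), config=cfg)
        s2, _ = admm_fit(X, y, lam, weights=marginal_weights(X, y, gamma=0.0), config=cfg)
        np.testing.assert_array_equal(s1.theta, s2.theta)

    def test_training_loss_nondecreasing_in_lambda(self, rng):
        n, q = 30, 20
        X = rng.normal(size=(n, q))
        y = rng.normal(size=n)
        lmax = lambda_max(X, y)
        cfg = FitConfig(eps_admm=1e-7)
        losses = []
        for frac in [0.01, 0.05, 0.1, 0.3, 0.6, 0.9]:
            state, _ = admm_fit(X, y, frac * lmax, config=cfg)
            losses.append(0.5 * np.sum((X @ state.theta - y) ** 2))
        assert all(b >= a - 1e-8 for a, b in zip(losses, losses[1:]))

    def test_nonconvergence_flagged_not_raised(self, rng):
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        state, diag = admm_fit(
            X, y, 0.01 * lambda_max(X, y), config=FitConfig(max_iter=2)
        )
        assert not diag.converged
        assert diag.n_iter == 2

    def test_invalid_lambda(self, rng):
        with pytest.raises(ValueError):
            admm_fit(np.eye(2), np.ones(2), -1.0)

    def test_linesearch_once_switch(self, rng):
        X = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        lam = 0.5 * lambda_max(X, y)
        cfg = FitConfig(eps_admm=1e-6, linesearch_per_iteration=False)
        state, diag = admm_fit(X, y, lam, config=cfg)
        assert diag.converged
        assert kkt_residual(X, y, state.theta, lam) < 1e-3
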