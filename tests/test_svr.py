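"""Tests of the Gaussian-kernel SVR core: kernel, scaling, dual training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from ecgi.exceptions import DegenerateInputError, ValidationError
from ecgi.svr import (GaussianSVR, MultiOutputGaussianSVR, SvrHyperparams,
                      gaussian_gram, gaussian_kernel, predict_svr, scale_bsp,
                      scale_bsp_columns, train_multi_output, train_svr)


def qp_dual_oracle(K, y, C, eps):
    """Independent generic-QP solve of the ε-SVR dual (SLSQP on the 2n-dim
    (α, α*) box with the equality constraint); returns the optimal dual
    objective value."""
    n = len(y)

    def negdual(z):
        b = z[:n] - z[n:]
        return 0.5 * b @ K @ b - y @ b + eps * z.sum()

    def grad(z):
        b = z[:n] - z[n:]
        g = K @ b
        return np.concatenate([g - y + eps, -g + y + eps])

    cons = [{"type": "eq",
             "fun": lambda z: np.sum(z[:n] - z[n:]),
             "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])}]
    res = minimize(negdual, np.zeros(2 * n), jac=grad,
                   bounds=[(0, C)] * (2 * n), constraints=cons,
                   method="SLSQP", options={"maxiter": 500, "ftol": 1e-12})
    return -res.fun


class TestKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(0, 1, 5)
        assert gaussian_kernel(x, x, 2.0) == 1.0

    def test_closed_form_at_sigma_distance(self):
        # ||xi - xj||^2 = 2 sigma^2  ->  exp(-1)
        sigma = 1.7
        xi = np.zeros(3)
        xj = np.array([np.sqrt(2) * sigma, 0.0, 0.0])
        assert gaussian_kernel(xi, xj, sigma) == pytest.approx(np.exp(-1), rel=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_bounds(self, seed):
        r = np.random.default_rng(seed)
        xi, xj = r.normal(0, 3, 4), r.normal(0, 3, 4)
        k = gaussian_kernel(xi, xj, 0.8)
        assert k == gaussian_kernel(xj, xi, 0.8)
        assert 0 < k <= 1

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_kernel(np.zeros(3), np.zeros(4), 1.0)


class TestScaling:
    def test_simple_vector(self):
        scaled, spec = scale_bsp(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(scaled, [0.0, 0.5, 1.0])
        assert spec.vmin == 1.0 and spec.vmax == 3.0

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            scale_bsp(np.array([5.0, 5.0, 5.0]))

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_order_preserved(self, seed):
        v = np.random.default_rng(seed).normal(0, 10, 12)
        scaled, _ = scale_bsp(v)
        np.testing.assert_array_equal(np.argsort(scaled, kind="stable"),
                                      np.argsort(v, kind="stable"))
        assert scaled.min() == 0.0 and scaled.max() == 1.0

    def test_idempotent_on_unit_range(self):
        v = np.array([0.0, 0.3, 0.7, 1.0])
        scaled, _ = scale_bsp(v)
        np.testing.assert_allclose(scaled, v, atol=1e-15)

    def test_columnwise_matches_per_column(self, rng):
        B = rng.normal(0, 2, (6, 5))
        out = scale_bsp_columns(B)
        for j in range(5):
            np.testing.assert_allclose(out[:, j], scale_bsp(B[:, j])[0])


class TestTrainSvr:
    def test_constant_targets_predicted_exactly(self, rng):
        X = rng.normal(0, 1, (10, 2))
        m = train_svr(X, np.full(10, 3.5), SvrHyperparams(C=1.0, sigma=1.0,
                                                          epsilon=0.1))
        np.testing.assert_allclose(m.predict(X), 3.5, atol=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_dual_objective_matches_qp_oracle(self, seed):
        r = np.random.default_rng(seed)
        n, d = int(r.integers(5, 15)), int(r.integers(1, 4))
        X, y = r.normal(0, 1, (n, d)), r.normal(0, 1, n)
        hp = SvrHyperparams(C=float(10 ** r.uniform(-1, 2)),
                            sigma=float(10 ** r.uniform(-0.5, 0.5)),
                            epsilon=float(r.uniform(0, 0.3)))
        m = GaussianSVR(C=hp.C, sigma=hp.sigma, epsilon=hp.epsilon,
                        tol=1e-10).fit(X, y)
        oracle = qp_dual_oracle(gaussian_gram(X, sigma=hp.sigma), y,
                                hp.C, hp.epsilon)
        assert m.dual_objective_ == pytest.approx(oracle, rel=1e-4, abs=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_dual_feasibility_and_kkt(self, seed):
        r = np.random.default_rng(100 + seed)
        X, y = r.normal(0, 1, (15, 2)), r.normal(0, 1, 15)
        C, eps = 5.0, 0.05
        m = GaussianSVR(C=C, sigma=1.0, epsilon=eps, tol=1e-10).fit(X, y)
        beta = m.dual_coefficients_
        assert np.all(np.abs(beta) <= C + 1e-9)
        assert abs(beta.sum()) <= 1e-8 * max(1.0, C)
        # KKT: points off the support set lie inside the epsilon tube
        full = np.zeros(15)
        full[m.support_] = beta
        f = m.predict(X)
        inside = np.abs(full) < 1e-9
        assert np.all(np.abs(f[inside] - y[inside]) <= eps + 1e-6)

    def test_laplacian_loss_is_epsilon_zero(self, rng):
        """ε = 0 training drops the tube term from the dual objective."""
        X, y = rng.normal(0, 1, (12, 2)), rng.normal(0, 1, 12)
        m = GaussianSVR(C=2.0, sigma=1.0, epsilon=0.0, tol=1e-10).fit(X, y)
        K = gaussian_gram(X, sigma=1.0)
        oracle = qp_dual_oracle(K, y, 2.0, 0.0)
        assert m.dual_objective_ == pytest.approx(oracle, rel=1e-4, abs=1e-8)

    def test_near_interpolation_at_training_points(self, rng):
        X = rng.uniform(-1, 1, (5, 1))
        y = np.sin(2 * X[:, 0])
        eps = 0.01
        m = GaussianSVR(C=1e4, sigma=1.0, epsilon=eps, tol=1e-10).fit(X, y)
        assert np.all(np.abs(m.predict(X) - y) <= eps + 1e-6)


class TestPredict:
    def test_zero_coefficients_return_bias(self, rng):
        X, y = rng.normal(0, 1, (8, 2)), np.full(8, 1.25)
        m = train_svr(X, y, SvrHyperparams(C=1.0, sigma=1.0, epsilon=0.5))
        # constant targets within the tube: all duals zero, prediction = b
        assert np.allclose(m.dual_coefficients_, 0.0)
        assert predict_svr(m, rng.normal(0, 1, 2)) == pytest.approx(m.bias_)

    def test_batch_equals_per_point(self, rng):
        X, y = rng.normal(0, 1, (10, 3)), rng.normal(0, 1, 10)
        m = train_svr(X, y, SvrHyperparams())
        Z = rng.normal(0, 1, (6, 3))
        batch = m.predict(Z)
        loop = [predict_svr(m, z) for z in Z]
        np.testing.assert_allclose(batch, loop, rtol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        m = train_svr(rng.normal(0, 1, (5, 3)), rng.normal(0, 1, 5),
                      SvrHyperparams())
        with pytest.raises(ValidationError):
            m.predict(rng.normal(0, 1, (2, 4)))


class TestMultiOutput:
    def test_columns_match_standalone_fits(self, rng):
        X = rng.normal(0, 1, (12, 2))
        Y = rng.normal(0, 1, (12, 3))
        hp = SvrHyperparams(C=3.0, sigma=0.8, epsilon=0.05)
        bank = train_multi_output(X, Y, hp, tol=1e-8)
        Z = rng.normal(0, 1, (5, 2))
        pred = bank.predict(Z)
        for j in range(3):
            solo = train_svr(X, Y[:, j], hp, tol=1e-8)
            np.testing.assert_allclose(pred[:, j], solo.predict(Z),
                                       rtol=1e-6, atol=1e-8)

    def test_duplicated_columns_identical_models(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = rng.normal(0, 1, 10)
        bank = train_multi_output(X, np.column_stack([y, y]),
                                  SvrHyperparams(), tol=1e-8)
        np.testing.assert_array_equal(bank.models_[0].dual_coefficients_,
                                      bank.models_[1].dual_coefficients_)

    def test_single_column_equals_train_svr(self, rng):
        X, y = rng.normal(0, 1, (9, 2)), rng.normal(0, 1, 9)
        hp = SvrHyperparams()
        bank = train_multi_output(X, y[:, None], hp, tol=1e-8)
        solo = train_svr(X, y, hp, tol=1e-8)
        np.testing.assert_allclose(bank.predict(X)[:, 0], solo.predict(X),
                                   rtol=1e-8)
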