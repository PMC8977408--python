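import numpy as np
import pytest

from myofuse.gpr import (
    DegenerateTargetError,
    GPRModel,
    KernelParams,
    OptConfig,
    fit_gpr,
    load_model,
    predict_mean,
    rq_kernel,
    save_model,
)


def brute_force_posterior_mean(X, y, X_new, params):
    """Independent dense GP posterior mean: standardize, build the Gram
    matrix entry by entry with the scalar kernel, solve, de-standardize."""
    xm, xs = X.mean(0), X.std(0)
    xs = np.where(xs == 0, 1.0, xs)
    ym, ysd = y.mean(), y.std()
    Xs, ys_ = (X - xm) / xs, (y - ym) / ysd
    Xn = (X_new - xm) / xs
    n = len(ys_)
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = rq_kernel(Xs[i], Xs[j], params)
    K[np.diag_indices(n)] += params.noise_sd**2 + 1e-10
    alpha = np.linalg.solve(K, ys_)
    Kx = np.array(
        [[rq_kernel(xn, xt, params) for xt in Xs] for xn in Xn]
    )
    return ym + ysd * (Kx @ alpha)


class TestKernel:
    def test_zero_distance_gives_sigma_squared(self):
        p = KernelParams(2.0, 1.5, 0.7, 0.0)
        x = np.array([0.3, -1.2, 4.0])
        assert rq_kernel(x, x, p) == pytest.approx(4.0)

    def test_unit_params_arithmetic(self):
        # sigma=1, alpha=1, l=1, r^2=2 -> (1 + 2/2)^-1 = 0.5
        p = KernelParams(1.0, 1.0, 1.0, 0.0)
        assert rq_kernel(np.array([0.0, 0.0]), np.array([1.0, 1.0]), p) == (
            pytest.approx(0.5)
        )

    def test_large_alpha_approaches_squared_exponential(self):
        p = KernelParams(1.0, 1e6, 1.0, 0.0)
        val = rq_kernel(np.array([0.0]), np.array([1.0]), p)
        assert val == pytest.approx(np.exp(-0.5), abs=1e-5)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        p = KernelParams(1.3, 0.8, 2.0, 0.0)
        x, y = rng.standard_normal((2, 5))
        assert rq_kernel(x, y, p) == rq_kernel(y, x, p)

    def test_invalid_params_rejected(self):
        for bad in [(0, 1, 1, 0), (1, -1, 1, 0), (1, 1, 0, 0), (1, 1, 1, -1)]:
            with pytest.raises(ValueError):
                KernelParams(*bad)

    def test_gram_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        p = KernelParams(1.0, 2.0, 1.5, 0.0)
        K = np.array([[rq_kernel(a, b, p) for b in X] for a in X])
        np.testing.assert_allclose(K, K.T)
        eig = np.linalg.eigvalsh(K)
        assert eig.min() >= -1e-8 * np.trace(K)


class TestFit:
    def test_degenerate_target_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(DegenerateTargetError):
            fit_gpr(rng.standard_normal((20, 2)), np.full(20, 3.0))

    def test_noiseless_smooth_function_fits_small_noise(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, (200, 1))
        y = np.sin(2.0 * X[:, 0]) + 0.3 * X[:, 0] ** 2
        model = fit_gpr(X, y, OptConfig(seed=0))
        assert model.params.noise_sd < 0.05  # standardized target has SD 1

    def test_fit_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + 0.1 * rng.standard_normal(60)
        m1 = fit_gpr(X, y, OptConfig(seed=7))
        m2 = fit_gpr(X, y, OptConfig(seed=7))
        assert m1.params == m2.params
        np.testing.assert_array_equal(m1.alpha_vec, m2.alpha_vec)

    def test_parameter_recovery_from_known_gp(self):
        """Data from a known RQ-GP: length_scale within x2, noise +-50%."""
        true = KernelParams(1.0, 2.0, 1.0, 0.1)
        ls, ns = [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.uniform(-3, 3, (300, 2))
            D2 = (
                np.sum(X * X, 1)[:, None]
                + np.sum(X * X, 1)[None, :]
                - 2 * X @ X.T
            )
            K = true.sigma**2 * (
                1 + np.maximum(D2, 0) / (2 * true.alpha * true.length_scale**2)
            ) ** (-true.alpha)
            L = np.linalg.cholesky(K + 1e-10 * np.eye(300))
            y = L @ rng.standard_normal(300) + true.noise_sd * (
                rng.standard_normal(300)
            )
            m = fit_gpr(X, y, OptConfig(seed=seed))
            # X is ~uniform: standardization shrinks scales by sd(X)~1.73
            ls.append(m.params.length_scale * X.std())
            ns.append(m.params.noise_sd * y.std())
        ls, ns = np.median(ls), np.median(ns)
        assert 0.5 <= ls <= 2.0, ls
        assert 0.05 <= ns <= 0.15, ns


class TestPredict:
    def test_interpolates_training_points_at_zero_noise(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 3))
        y = np.cos(X[:, 0]) + X[:, 1]
        model = fit_gpr(X, y, params=KernelParams(1.0, 1.0, 1.0, 0.0))
        pred = predict_mean(model, X)
        np.testing.assert_allclose(pred, y, rtol=1e-6, atol=1e-6)

    def test_far_inputs_revert_to_training_mean(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 2))
        y = X[:, 0] * 2.0 + 5.0
        model = fit_gpr(X, y, params=KernelParams(1.0, 1.0, 0.5, 0.1))
        far = np.full((3, 2), 500.0)
        np.testing.assert_allclose(
            predict_mean(model, far), y.mean(), atol=1e-3 * np.abs(y.mean())
        )

    def test_matches_bruteforce_dense_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((25, 4))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(25)
        X_new = rng.standard_normal((10, 4))
        p = KernelParams(1.2, 0.9, 1.4, 0.05)
        model = fit_gpr(X, y, params=p)
        expected = brute_force_posterior_mean(X, y, X_new, p)
        np.testing.assert_allclose(
            predict_mean(model, X_new), expected, atol=1e-8
        )

    def test_matches_sklearn_at_fixed_hyperparameters(self):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RationalQuadratic

        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 3))
        y = X[:, 0] - 0.5 * X[:, 2] + 0.05 * rng.standard_normal(40)
        p = KernelParams(1.0, 1.3, 0.9, 0.1)
        model = fit_gpr(X, y, params=p)
        # feed sklearn the standardized problem our model solves internally
        Xs = (X - model.x_mean) / model.x_sd
        ys = (y - model.y_mean) / model.y_sd
        gp = GaussianProcessRegressor(
            kernel=RationalQuadratic(length_scale=p.length_scale, alpha=p.alpha),
            alpha=p.noise_sd**2,
            optimizer=None,
        )
        gp.fit(Xs, ys)
        X_new = rng.standard_normal((12, 3))
        ours = predict_mean(model, X_new)
        theirs = model.y_mean + model.y_sd * gp.predict(
            (X_new - model.x_mean) / model.x_sd
        )
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_scaling_covariance(self):
        """Scaling y by c scales predictions by c at fixed hyperparameters."""
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 2))
        y = np.tanh(X[:, 0]) + 0.1 * rng.standard_normal(30)
        p = KernelParams(1.0, 1.0, 1.0, 0.05)
        X_new = rng.standard_normal((8, 2))
        base = predict_mean(fit_gpr(X, y, params=p), X_new)
        scaled = predict_mean(fit_gpr(X, 3.5 * y, params=p), X_new)
        np.testing.assert_allclose(scaled, 3.5 * base, rtol=1e-9)

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((20, 3))
        model = fit_gpr(X, X[:, 0], params=KernelParams(1, 1, 1, 0.1))
        with pytest.raises(ValueError):
            predict_mean(model, rng.standard_normal((5, 4)))


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((30, 2))
        y = X[:, 0] + 0.1 * rng.standard_normal(30)
        model = fit_gpr(X, y, OptConfig(seed=1))
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        X_new = rng.standard_normal((5, 2))
        np.testing.assert_allclose(
            predict_mean(loaded, X_new), predict_mean(model, X_new)
        )
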