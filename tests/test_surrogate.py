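import numpy as np
import pytest

from grnabc.surrogate import (
    KernelHyperparams,
    combined_kernel,
    holdout_diagnostic,
    rq_kernel,
    train_surrogate,
    white_kernel,
    load_surrogate,
    save_surrogate,
)


def dense_gp_oracle(X, y, x_star, hp: KernelHyperparams):
    """Closed-form GP prediction via dense linear algebra, independent of
    the sklearn path: K = RQ + gamma*I on training points; the white term
    contributes to the predictive variance (noisy-observation prediction)
    but not to cross-covariances."""
    n = len(X)
    K = np.array([[rq_kernel(X[i], X[j], hp.l, hp.alpha) for j in range(n)] for i in range(n)])
    K += hp.gamma_noise * np.eye(n)
    k_star = np.array([rq_kernel(x_star, X[j], hp.l, hp.alpha) for j in range(n)])
    alpha_vec = np.linalg.solve(K, y)
    mean = k_star @ alpha_vec
    var = 1.0 + hp.gamma_noise - k_star @ np.linalg.solve(K, k_star)
    return mean, np.sqrt(max(var, 0.0))


class TestKernels:
    def test_rq_at_zero_distance_is_one(self):
        assert rq_kernel([0.3, -1.2], [0.3, -1.2], l=0.7, alpha=2.0) == 1.0

    def test_rq_closed_form_value(self):
        # ||x - x'|| = sqrt(2), l = alpha = 1: (1 + 2/2)^-1 = 0.5
        assert rq_kernel([0.0, 0.0], [1.0, 1.0], l=1.0, alpha=1.0) == pytest.approx(0.5)

    def test_rq_squared_exponential_limit(self):
        # alpha -> inf at fixed d, l: k -> exp(-d^2 / (2 l^2))
        d2 = 1.7**2
        x, x2 = [0.0, 0.0], [1.7, 0.0]
        val = rq_kernel(x, x2, l=0.9, alpha=1e6)
        assert val == pytest.approx(np.exp(-d2 / (2 * 0.9**2)), rel=1e-4)

    def test_rq_symmetric_decreasing(self):
        a = rq_kernel([0, 0], [1, 0], 1.0, 1.0)
        b = rq_kernel([0, 0], [2, 0], 1.0, 1.0)
        assert rq_kernel([1, 0], [0, 0], 1.0, 1.0) == a
        assert 0 < b < a <= 1

    def test_white_kernel(self):
        assert white_kernel([1, 2], [1, 2], 0.3) == 0.3
        assert white_kernel([1, 2], [1, 2.00001], 0.3) == 0.0
        assert combined_kernel([1, 2], [1, 2], 1.0, 1.0, 0.3) == pytest.approx(1.3)

    def test_gram_matrices_positive_semidefinite(self, rng):
        X = rng.normal(size=(30, 2))
        for l, alpha, g in [(0.5, 1.0, 0.0), (2.0, 0.3, 0.05)]:
            K = np.array(
                [[combined_kernel(a, b, l, alpha, g) for b in X] for a in X]
            )
            eig = np.linalg.eigvalsh(K)
            assert eig.min() >= -1e-8


class TestTrainingAndPrediction:
    def test_matches_dense_oracle_at_fixed_hyperparams(self, rng):
        hp = KernelHyperparams(l=0.8, alpha=1.5, gamma_noise=0.05)
        X = rng.uniform(-2, 2, size=(25, 2))
        y = np.sin(X[:, 0]) + 0.3 * X[:, 1]
        surr = train_surrogate(X, y, optimize=False, init=hp, normalize_y=False)
        for _ in range(10):
            x_star = rng.uniform(-2, 2, size=2)
            mean, sd = surr.predict(x_star)
            mean_o, sd_o = dense_gp_oracle(X, y, x_star, hp)
            assert mean == pytest.approx(mean_o, abs=1e-6)
            assert sd == pytest.approx(sd_o, abs=1e-6)

    def test_noise_free_linear_interpolation(self, rng):
        X = rng.uniform(-1, 1, size=(60, 2))
        y = 2.0 * X[:, 0] - 0.5 * X[:, 1] + 1.0
        surr = train_surrogate(X, y, restarts=2, seed=0)
        x_star = np.array([[0.1, -0.2], [0.0, 0.3], [-0.25, 0.15]])
        mean, _ = surr.predict_batch(x_star)
        want = 2.0 * x_star[:, 0] - 0.5 * x_star[:, 1] + 1.0
        assert np.allclose(mean, want, rtol=0.01, atol=0.01)

    def test_hyperparameter_recovery_on_synthetic_draw(self, rng):
        hp = KernelHyperparams(l=0.5, alpha=2.0, gamma_noise=0.01)
        X = rng.uniform(-3, 3, size=(200, 2))
        K = np.array(
            [[rq_kernel(a, b, hp.l, hp.alpha) for b in X] for a in X]
        ) + hp.gamma_noise * np.eye(200)
        y = np.linalg.cholesky(K) @ rng.standard_normal(200)
        surr = train_surrogate(X, y, restarts=3, seed=1)
        assert hp.l / 2 <= surr.hyperparams.l <= hp.l * 2

    def test_duplicated_inconsistent_point_forces_noise(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        y = np.array([0.0, 1.0, 0.5])
        surr = train_surrogate(X, y, restarts=2, seed=0)
        assert surr.hyperparams.gamma_noise > 1e-4

    def test_training_improves_log_marginal_likelihood(self, rng):
        X = rng.uniform(-2, 2, size=(40, 2))
        y = np.cos(X[:, 0]) + 0.1 * rng.standard_normal(40)
        init = KernelHyperparams(l=1.0, alpha=1.0, gamma_noise=0.1)
        fixed = train_surrogate(X, y, optimize=False, init=init)
        fitted = train_surrogate(X, y, restarts=2, seed=0, init=init)
        assert fitted.log_marginal_likelihood >= fixed.log_marginal_likelihood - 1e-6

    def test_permutation_invariance(self, rng):
        X = rng.uniform(-2, 2, size=(30, 2))
        y = X[:, 0] ** 2 + rng.normal(0, 0.05, 30)
        perm = rng.permutation(30)
        a = train_surrogate(X, y, restarts=1, seed=0)
        b = train_surrogate(X[perm], y[perm], restarts=1, seed=0)
        x_star = np.array([0.3, -0.7])
        assert a.predict(x_star)[0] == pytest.approx(b.predict(x_star)[0], abs=1e-6)

    def test_sd_ordering_between_data_and_gaps(self, rng):
        X = np.array([[-2.0, 0.0], [2.0, 0.0]])
        y = np.array([1.0, 2.0])
        surr = train_surrogate(
            X, y, optimize=False,
            init=KernelHyperparams(l=0.5, alpha=1.0, gamma_noise=1e-6),
            normalize_y=False,
        )
        sd_at_data = surr.predict(np.array([-2.0, 0.0]))[1]
        sd_mid = surr.predict(np.array([0.0, 0.0]))[1]
        assert sd_at_data < sd_mid

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            train_surrogate(np.zeros((5, 2)), np.arange(5.0))
        with pytest.raises(ValueError):
            train_surrogate(np.array([[0.0, 1.0]]), np.array([1.0]))
        with pytest.raises(ValueError):
            train_surrogate(
                np.array([[0.0, 1.0], [np.nan, 0.0]]), np.array([1.0, 2.0])
            )


class TestSampling:
    def test_zero_sd_returns_mean(self, rng):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        surr = train_surrogate(
            X, np.array([1.0, 2.0]), optimize=False,
            init=KernelHyperparams(l=1.0, alpha=1.0, gamma_noise=1e-12),
            normalize_y=False,
        )
        mean, sd = surr.predict(np.array([0.0, 0.0]))
        draws = [surr.sample_distance(np.array([0.0, 0.0]), rng) for _ in range(5)]
        assert np.allclose(draws, draws[0], atol=5 * sd + 1e-9)

    def test_draws_nonnegative_and_mean_consistent(self, rng):
        X = rng.uniform(-1, 1, size=(20, 2))
        y = 3.0 + 0.5 * rng.standard_normal(20)
        surr = train_surrogate(X, y, restarts=1, seed=0)
        theta = np.array([0.2, 0.2])
        mean, sd = surr.predict(theta)
        draws = np.array([surr.sample_distance(theta, rng) for _ in range(10_000)])
        assert (draws >= 0).all()
        if mean / sd > 3:  # truncation mass negligible
            assert draws.mean() == pytest.approx(mean, abs=3 * sd / 100)


class TestDiagnosticsAndIO:
    def test_holdout_diagnostic_reports(self, rng):
        X = rng.uniform(-2, 2, size=(60, 2))
        y = np.sin(X[:, 0]) + 0.05 * rng.standard_normal(60)
        diag = holdout_diagnostic(X, y, seed=0)
        assert set(diag) >= {"n_holdout", "frac_large_z", "flagged"}
        assert 0.0 <= diag["frac_large_z"] <= 1.0

    def test_archive_round_trip(self, tmp_path, rng):
        X = rng.uniform(-1, 1, size=(15, 2))
        y = X[:, 0] + 0.1 * rng.standard_normal(15)
        surr = train_surrogate(X, y, restarts=1, seed=0)
        path = save_surrogate(surr, tmp_path / "surr.json")
        loaded = load_surrogate(path)
        x_star = np.array([0.3, 0.1])
        assert loaded.predict(x_star)[0] == pytest.approx(surr.predict(x_star)[0], rel=1e-6)
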