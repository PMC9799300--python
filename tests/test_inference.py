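import numpy as np
import pytest
from scipy import stats

from grnabc.core import PriorSpec
from grnabc.inference import (
    InferenceFailure,
    Posterior,
    SMCConfig,
    abc_rejection,
    abc_smc,
)

PRIOR = PriorSpec()


def deterministic_log_distance(theta_star):
    target = np.log10(np.asarray(theta_star, float))

    def fn(thetas, rng):
        return np.linalg.norm(np.log10(np.atleast_2d(thetas)) - target, axis=1)

    return fn


def uniform_noise_distance(thetas, rng):
    return rng.uniform(0.0, 1.0, size=len(np.atleast_2d(thetas)))


class TestRejection:
    def test_zero_distance_returns_prior(self):
        fn = lambda thetas, rng: np.zeros(len(np.atleast_2d(thetas)))
        lb = PRIOR.log_bounds()
        for attempt in range(3):
            post = abc_rejection(PRIOR, fn, epsilon=1.0, n_accept=4000, seed=10 + attempt)
            logs = np.log10(post.samples)
            ps = [
                stats.kstest(
                    (logs[:, a] - lb[a, 0]) / (lb[a, 1] - lb[a, 0]), "uniform"
                ).pvalue
                for a in range(2)
            ]
            if min(ps) > 0.01:
                return
        pytest.fail("degenerate-acceptance posterior does not match the prior")

    def test_small_epsilon_confines_to_log_ball(self):
        theta_star = (0.5, 2.0)
        post = abc_rejection(
            PRIOR, deterministic_log_distance(theta_star), epsilon=0.2,
            n_accept=50, seed=3, max_trials=500_000,
        )
        d = np.linalg.norm(np.log10(post.samples) - np.log10(theta_star), axis=1)
        assert (d <= 0.2).all()

    def test_acceptance_fraction_matches_quantile(self):
        # distance independent of theta, uniform on [0,1]: a threshold at q
        # accepts a fraction q of trials
        post = abc_rejection(
            PRIOR, uniform_noise_distance, epsilon=0.3, n_accept=3000,
            seed=0, max_trials=10_000,
        )
        assert post.acceptance_rates[0] == pytest.approx(0.3, abs=0.02)

    def test_no_acceptance_raises_with_diagnostics(self):
        fn = lambda thetas, rng: np.ones(len(np.atleast_2d(thetas)))
        with pytest.raises(InferenceFailure) as err:
            abc_rejection(PRIOR, fn, epsilon=0.5, n_accept=10, seed=0, max_trials=200)
        assert err.value.diagnostics["trials"] == 200


class TestSMC:
    def test_contract_weights_and_epsilon_schedule(self):
        cfg = SMCConfig(population=100, n_generations=4, pilot=300)
        post = abc_smc(PRIOR, uniform_noise_distance, cfg, seed=1)
        assert post.weights.sum() == pytest.approx(1.0)
        assert (np.diff(post.epsilons) <= 1e-12).all()
        assert len(post.samples) == 100
        # samples never escape the prior box
        assert ((post.samples[:, 0] >= 0.0039) & (post.samples[:, 0] <= 16)).all()
        assert ((post.samples[:, 1] >= 0.25) & (post.samples[:, 1] <= 16)).all()

    def test_recovers_known_minimum(self):
        theta_star = (0.5, 2.0)
        cfg = SMCConfig(population=200, n_generations=8)
        post = abc_smc(PRIOR, deterministic_log_distance(theta_star), cfg, seed=5)
        mean_log = post.weighted_mean_log()
        err = np.linalg.norm(mean_log - np.log10(theta_star))
        assert err < 0.1

    def test_theta_independent_distance_returns_prior(self):
        cfg = SMCConfig(population=400, n_generations=3, pilot=400)
        lb = PRIOR.log_bounds()
        for attempt in range(3):
            post = abc_smc(PRIOR, uniform_noise_distance, cfg, seed=30 + attempt)
            logs = np.log10(post.samples)
            # weighted resample to plain draws for the KS check
            rng = np.random.default_rng(0)
            idx = rng.choice(len(logs), size=400, p=post.weights)
            ps = [
                stats.kstest(
                    (logs[idx, a] - lb[a, 0]) / (lb[a, 1] - lb[a, 0]), "uniform"
                ).pvalue
                for a in range(2)
            ]
            if min(ps) > 0.01:
                return
        pytest.fail("SMC with uninformative distance should return the prior")

    def test_determinism(self):
        cfg = SMCConfig(population=64, n_generations=3, pilot=200)
        a = abc_smc(PRIOR, uniform_noise_distance, cfg, seed=9)
        b = abc_smc(PRIOR, uniform_noise_distance, cfg, seed=9)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.weights, b.weights)

    def test_population_validation(self):
        with pytest.raises(ValueError):
            SMCConfig(population=5)
        with pytest.raises(ValueError):
            SMCConfig(quantile=1.5)


class TestDirectSimulationMode:
    def test_direct_mode_agrees_with_surrogate_mode(self):
        # tiny well-mixed problem: ABC-SMC simulating at every proposal
        # lands within 0.5 log10 units of the surrogate-driven posterior
        from dataclasses import replace

        from grnabc.core import make_grid
        from grnabc.datasets import generate_grid_data
        from grnabc.distances import DistanceMetricSpec
        from grnabc.inference import simulator_distance_fn, surrogate_distance_fn
        from grnabc.pipeline import surrogate_training_set
        from grnabc.simulators import SimulationConfig
        from grnabc.surrogate import train_surrogate

        cfg = SimulationConfig(t_burn=100.0, n_samples=10, dt_sample=5.0, seed=9)
        data = generate_grid_data(make_grid(3, 3), "WMM", 4, cfg)
        obs = data[4]  # middle grid node as observed data
        metric = DistanceMetricSpec("kolmogorov")
        X, y = surrogate_training_set(obs, data, metric)
        surr = train_surrogate(X, y, restarts=2, seed=0)
        smc = SMCConfig(population=60, n_generations=3, pilot=200)
        post_surr = abc_smc(PRIOR, surrogate_distance_fn(surr), smc, seed=3)
        post_direct = abc_smc(
            PRIOR, simulator_distance_fn(obs, "WMM", metric, cfg, n_traj=4), smc, seed=3
        )
        gap = np.linalg.norm(
            post_surr.weighted_mean_log() - post_direct.weighted_mean_log()
        )
        assert gap < 0.5


class TestPosteriorType:
    def test_weight_normalisation_enforced(self):
        with pytest.raises(ValueError):
            Posterior(samples=np.ones((2, 2)), weights=np.array([0.5, 0.4]))

    def test_epsilon_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            Posterior(
                samples=np.ones((2, 2)),
                weights=np.array([0.5, 0.5]),
                epsilons=(1.0, 2.0),
            )

    def test_credible_box_contains_bulk(self):
        rng = np.random.default_rng(0)
        samples = 10 ** rng.normal(0, 0.1, size=(500, 2))
        post = Posterior(samples=samples, weights=np.full(500, 1 / 500))
        box = post.credible_box(0.9)
        inside = (
            (samples[:, 0] >= box[0, 0]) & (samples[:, 0] <= box[0, 1])
            & (samples[:, 1] >= box[1, 0]) & (samples[:, 1] <= box[1, 1])
        )
        assert 0.7 < inside.mean() <= 1.0
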