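"""ABC rejection and ABC-SMC posterior estimation over (D, chi).

The sampler runs in log10-parameter space, where the prior is a uniform
box.  Distance backends are vectorised: a backend maps an (m, 2) array of
(D, chi) proposals to m (possibly stochastic) distances, so the surrogate
mode amortises GP prediction over whole proposal batches.  Distances come
either from a fitted surrogate (the pipeline's mode — zero simulator calls
during inference) or from direct simulation at every proposal (small-scale
validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import PriorSpec
from .datasets import TrajectoryEnsemble, generate_ensemble, select_species
from .distances import DistanceMetricSpec, make_distance
from .surrogate import DistanceSurrogate


class InferenceFailure(RuntimeError):
    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class SMCConfig:
    population: int = 200
    n_generations: int = 8
    quantile: float = 0.5  # epsilon = this quantile of accepted distances
    kernel_scale: float = 2.0  # perturbation cov = scale * weighted cov
    pilot: int = 1000  # prior draws fixing the initial epsilon
    final_epsilon: float | None = None  # optional early-stop threshold
    max_trials_factor: int = 2000
    min_ess: float = 5.0

    def __post_init__(self) -> None:
        if self.population < 10:
            raise ValueError("population must be >= 10")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")


@dataclass(frozen=True)
class Posterior:
    """Weighted (D, chi) samples plus the SMC acceptance trace."""

    samples: np.ndarray  # (m, 2) columns (D, chi), linear scale
    weights: np.ndarray  # (m,) non-negative, sums to 1
    epsilons: tuple[float, ...] = ()
    acceptance_rates: tuple[float, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.weights):
            raise ValueError("samples and weights must align")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        eps = np.asarray(self.epsilons)
        if len(eps) > 1 and (np.diff(eps) > 1e-12).any():
            raise ValueError("epsilon schedule must be non-increasing")

    @property
    def log_samples(self) -> np.ndarray:
        return np.log10(self.samples)

    def weighted_mean_log(self) -> np.ndarray:
        return self.log_samples.T @ self.weights

    def credible_box(self, level: float = 0.9) -> np.ndarray:
        """Weighted marginal quantile box [(lo, hi) per axis], linear scale."""
        alpha = (1.0 - level) / 2.0
        out = np.empty((2, 2))
        for axis in range(2):
            order = np.argsort(self.samples[:, axis])
            cum = np.cumsum(self.weights[order])
            cum /= cum[-1]
            vals = self.samples[order, axis]
            out[axis, 0] = vals[np.searchsorted(cum, alpha)]
            out[axis, 1] = vals[min(np.searchsorted(cum, 1.0 - alpha), len(vals) - 1)]
        return out


def _prior_batch(rng: np.random.Generator, lb: np.ndarray, m: int) -> np.ndarray:
    return rng.uniform(lb[:, 0], lb[:, 1], size=(m, 2))


def abc_rejection(
    prior: PriorSpec,
    distance_fn,
    epsilon: float,
    n_accept: int,
    seed: int,
    max_trials: int | None = None,
    batch: int = 512,
) -> Posterior:
    """Plain rejection ABC: accept prior draws with distance <= epsilon."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if n_accept < 1:
        raise ValueError("n_accept must be >= 1")
    rng = np.random.default_rng(seed)
    lb = prior.log_bounds()
    max_trials = max_trials or 2000 * n_accept
    accepted: list[np.ndarray] = []
    trials = 0
    while sum(len(a) for a in accepted) < n_accept and trials < max_trials:
        m = min(batch, max_trials - trials)
        logs = _prior_batch(rng, lb, m)
        thetas = 10.0**logs
        d = np.asarray(distance_fn(thetas, rng))
        trials += m
        accepted.append(thetas[d <= epsilon])
    samples = np.concatenate(accepted) if accepted else np.empty((0, 2))
    if len(samples) == 0:
        raise InferenceFailure(
            f"no acceptances in {trials} trials at epsilon={epsilon}",
            {"trials": trials, "epsilon": epsilon},
        )
    samples = samples[:n_accept]
    m = len(samples)
    return Posterior(
        samples=samples,
        weights=np.full(m, 1.0 / m),
        epsilons=(epsilon,),
        acceptance_rates=(m / trials,),
    )


def abc_smc(prior: PriorSpec, distance_fn, config: SMCConfig, seed: int) -> Posterior:
    """ABC-SMC with an adaptive quantile epsilon schedule.

    Generation 0 samples the prior with the initial epsilon set at the
    configured quantile of a pilot batch of prior-level distances; later
    generations resample the previous population, perturb with a Gaussian
    kernel in log space (covariance = kernel_scale times the weighted
    population covariance, proposals outside the prior box redrawn), accept
    below the current epsilon, and tighten epsilon to the quantile of the
    accepted distances.  Importance weights follow the standard SMC kernel
    correction (the log-space prior is flat, so weights reduce to inverse
    kernel mixture densities).
    """
    rng = np.random.default_rng(seed)
    lb = prior.log_bounds()
    n = config.population

    pilot_d = np.asarray(distance_fn(10.0 ** _prior_batch(rng, lb, config.pilot), rng))
    epsilon = float(np.quantile(pilot_d, config.quantile))

    log_particles = np.empty((n, 2))
    weights = np.full(n, 1.0 / n)
    epsilons: list[float] = []
    acc_rates: list[float] = []

    for gen in range(config.n_generations):
        if gen > 0:
            cov = config.kernel_scale * np.cov(log_particles.T, aweights=weights)
            cov += 1e-10 * np.eye(2)
            chol = np.linalg.cholesky(cov)
            inv_cov = np.linalg.inv(cov)
            norm_const = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(cov)))
        new_particles = np.empty((n, 2))
        new_distances = np.empty(n)
        accepted = 0
        trials = 0
        max_trials = config.max_trials_factor * n
        batch = max(n, 256)
        while accepted < n:
            if trials >= max_trials:
                raise InferenceFailure(
                    f"SMC generation {gen} exhausted {trials} trials at "
                    f"epsilon={epsilon}",
                    {"generation": gen, "epsilon": epsilon, "trials": trials},
                )
            if gen == 0:
                props = _prior_batch(rng, lb, batch)
            else:
                props = np.empty((batch, 2))
                filled = 0
                while filled < batch:
                    idx = rng.choice(n, size=batch - filled, p=weights)
                    cand = log_particles[idx] + rng.standard_normal((batch - filled, 2)) @ chol.T
                    ok = (
                        (cand[:, 0] >= lb[0, 0])
                        & (cand[:, 0] <= lb[0, 1])
                        & (cand[:, 1] >= lb[1, 0])
                        & (cand[:, 1] <= lb[1, 1])
                    )
                    good = cand[ok]
                    props[filled : filled + len(good)] = good
                    filled += len(good)
            d = np.asarray(distance_fn(10.0**props, rng))
            trials += batch
            hits = np.flatnonzero(d <= epsilon)
            take = hits[: n - accepted]
            new_particles[accepted : accepted + len(take)] = props[take]
            new_distances[accepted : accepted + len(take)] = d[take]
            accepted += len(take)
        acc_rates.append(n / trials)
        epsilons.append(epsilon)
        if gen == 0:
            new_weights = np.full(n, 1.0 / n)
        else:
            diff = new_particles[:, None, :] - log_particles[None, :, :]  # (n, n, 2)
            quad = np.einsum("mij,jk,mik->mi", diff, inv_cov, diff)
            dens = norm_const * np.exp(-0.5 * quad)
            mixture = dens @ weights
            new_weights = 1.0 / np.maximum(mixture, 1e-300)
            new_weights /= new_weights.sum()
        ess = 1.0 / float((new_weights**2).sum())
        if ess < config.min_ess:
            raise InferenceFailure(
                f"population collapse at generation {gen}: ESS={ess:.2f}",
                {"generation": gen, "ess": ess, "epsilons": epsilons},
            )
        log_particles = new_particles
        weights = new_weights
        if config.final_epsilon is not None and epsilon <= config.final_epsilon:
            break
        epsilon = min(epsilon, float(np.quantile(new_distances, config.quantile)))

    return Posterior(
        samples=10.0**log_particles,
        weights=weights,
        epsilons=tuple(epsilons),
        acceptance_rates=tuple(acc_rates),
    )


# ---------------------------------------------------------------------------
# Distance backends
# ---------------------------------------------------------------------------

def surrogate_distance_fn(surrogate: DistanceSurrogate):
    """Vectorised backend sampling from the GP predictive distribution
    (normal truncated below at zero)."""

    def fn(thetas: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        mean, sd = surrogate.predict_batch(np.log10(np.atleast_2d(thetas)))
        draws = rng.normal(mean, sd)
        for _ in range(100):
            bad = draws < 0
            if not bad.any():
                break
            hopeless = bad & (mean / sd < -6.0)
            draws[hopeless] = 0.0
            bad &= ~hopeless
            if not bad.any():
                break
            draws[bad] = rng.normal(mean[bad], sd[bad])
        return np.maximum(draws, 0.0)

    return fn


def simulator_distance_fn(
    observed: TrajectoryEnsemble,
    model: str,
    metric: DistanceMetricSpec,
    sim_config,
    n_traj: int = 4,
):
    """Direct-simulation backend: simulate a small ensemble at each theta
    and measure the metric against the observed data (validation mode)."""
    dist = make_distance(metric)

    def one(D: float, chi: float, rng: np.random.Generator) -> float:
        seed = int(rng.integers(0, 2**31 - 1))
        sim = generate_ensemble(model, D, chi, n_traj, replace(sim_config, seed=seed))
        sim = replace(sim, times=observed.times)  # shared sampling layout
        if sim.species != observed.species:
            which = {("P",): "protein_only", ("mRNA",): "mrna_only"}[observed.species]
            sim = select_species(sim, which)
        return dist(observed, sim)

    def fn(thetas: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        thetas = np.atleast_2d(thetas)
        return np.array([one(D, chi, rng) for D, chi in thetas])

    return fn


def run_inference(
    observed: TrajectoryEnsemble,
    distance_fn,
    config: SMCConfig,
    seed: int,
    prior: PriorSpec | None = None,
    provenance: dict | None = None,
) -> Posterior:
    """ABC-SMC against an arbitrary distance backend, with provenance."""
    prior = prior or PriorSpec()
    post = abc_smc(prior, distance_fn, config, seed)
    prov = {
        "observed_model": observed.model,
        "observed_point": {"D": observed.D, "chi": observed.chi},
        "seed": seed,
        "population": config.population,
        "generations": config.n_generations,
    }
    prov.update(provenance or {})
    return Posterior(
        samples=post.samples,
        weights=post.weights,
        epsilons=post.epsilons,
        acceptance_rates=post.acceptance_rates,
        provenance=prov,
    )
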