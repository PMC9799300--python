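"""Gaussian-process surrogate of the distance metric over (log D, log chi).

The surrogate replaces all simulation during ABC: distances between the
observed ensemble and ensembles simulated across the prior range are
computed once, a GP is fitted to them in log10-parameter space, and ABC
then samples stochastic distances from the GP predictive distribution
(mean and standard deviation), mimicking the trajectory-to-trajectory
scatter of the true distance.

Kernel: rational quadratic plus white noise,

    k1(x, x') = (1 + d(x,x')^2 / (2 alpha l^2))^(-alpha)
    k2(x, x') = gamma_noise if x == x' else 0
    k = k1 + k2

fitted by maximising the log marginal likelihood with L-BFGS-B restarts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RationalQuadratic, WhiteKernel

SD_FLOOR = 1e-12


def rq_kernel(x, x2, l: float, alpha: float) -> float:
    """Rational-quadratic covariance between two points."""
    if l <= 0 or alpha <= 0:
        raise ValueError("l and alpha must be positive")
    d2 = float(np.sum((np.asarray(x, float) - np.asarray(x2, float)) ** 2))
    return (1.0 + d2 / (2.0 * alpha * l * l)) ** (-alpha)


def white_kernel(x, x2, gamma_noise: float) -> float:
    """White-noise covariance: gamma_noise on identical inputs, else 0."""
    if gamma_noise < 0:
        raise ValueError("gamma_noise must be non-negative")
    return gamma_noise if np.array_equal(np.asarray(x), np.asarray(x2)) else 0.0


def combined_kernel(x, x2, l: float, alpha: float, gamma_noise: float) -> float:
    return rq_kernel(x, x2, l, alpha) + white_kernel(x, x2, gamma_noise)


@dataclass(frozen=True)
class KernelHyperparams:
    l: float
    alpha: float
    gamma_noise: float

    def __post_init__(self) -> None:
        if self.l <= 0 or self.alpha <= 0 or self.gamma_noise < 0:
            raise ValueError("hyperparameters must be positive (noise >= 0)")


@dataclass
class DistanceSurrogate:
    """Fitted GP over (log10 D, log10 chi) -> distance."""

    inputs: np.ndarray  # (n, 2) log10 coordinates
    targets: np.ndarray  # (n,) distances
    hyperparams: KernelHyperparams
    gp: GaussianProcessRegressor
    log_marginal_likelihood: float

    def predict(self, theta_log: np.ndarray) -> tuple[float, float]:
        """Predictive mean and standard deviation at one log10 point."""
        mean, sd = self.gp.predict(np.atleast_2d(theta_log), return_std=True)
        return float(mean[0]), float(max(sd[0], SD_FLOOR))

    def predict_batch(self, theta_log: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean, sd = self.gp.predict(np.atleast_2d(theta_log), return_std=True)
        return mean, np.maximum(sd, SD_FLOOR)

    def sample_distance(self, theta_log: np.ndarray, rng: np.random.Generator) -> float:
        """One stochastic distance: Normal(mean, sd) truncated below at 0."""
        mean, sd = self.predict(theta_log)
        if sd <= SD_FLOOR:
            return max(mean, 0.0)
        while True:  # truncated normal by rejection; acceptance >= Phi(mean/sd)
            draw = rng.normal(mean, sd)
            if draw >= 0.0:
                return float(draw)
            if mean / sd < -6.0:  # essentially all mass below 0
                return 0.0


def train_surrogate(
    inputs: np.ndarray,
    distances: np.ndarray,
    restarts: int = 5,
    seed: int = 0,
    optimize: bool = True,
    init: KernelHyperparams | None = None,
    normalize_y: bool = True,
) -> DistanceSurrogate:
    """Fit the RQ+white GP by maximum marginal likelihood (L-BFGS-B).

    inputs are (n, 2) log10-(D, chi) coordinates; distances their raw-scale
    metric values.  With optimize=False the kernel is fixed at ``init``
    (used by diagnostics and cross-checks).
    """
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(distances, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or len(X) != len(y):
        raise ValueError("inputs must be (n, 2) with matching targets")
    if len(X) < 2:
        raise ValueError("need at least 2 training points")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite training data")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate training inputs (all identical)")
    init = init or KernelHyperparams(l=1.0, alpha=1.0, gamma_noise=0.1)
    kernel = RationalQuadratic(
        length_scale=init.l,
        alpha=init.alpha,
        length_scale_bounds=(1e-3, 1e3),
        alpha_bounds=(1e-3, 1e6),
    ) + WhiteKernel(noise_level=init.gamma_noise, noise_level_bounds=(1e-12, 1e3))
    gp = GaussianProcessRegressor(
        kernel=kernel,
        optimizer="fmin_l_bfgs_b" if optimize else None,
        n_restarts_optimizer=restarts if optimize else 0,
        normalize_y=normalize_y,
        random_state=seed,
    )
    gp.fit(X, y)
    k_rq, k_white = gp.kernel_.k1, gp.kernel_.k2
    hp = KernelHyperparams(
        l=float(k_rq.length_scale),
        alpha=float(k_rq.alpha),
        gamma_noise=float(k_white.noise_level),
    )
    return DistanceSurrogate(
        inputs=X,
        targets=y,
        hyperparams=hp,
        gp=gp,
        log_marginal_likelihood=float(gp.log_marginal_likelihood_value_),
    )


def holdout_diagnostic(
    inputs: np.ndarray,
    distances: np.ndarray,
    holdout_frac: float = 0.2,
    seed: int = 0,
    z_limit: float = 3.0,
    flag_frac: float = 0.05,
) -> dict:
    """Goodness-of-fit proxy: standardized residuals on a held-out split.

    Returns the fraction of held-out points with |z| > z_limit and a flag
    when that fraction exceeds flag_frac.
    """
    rng = np.random.default_rng(seed)
    n = len(distances)
    idx = rng.permutation(n)
    n_hold = max(1, int(holdout_frac * n))
    hold, train = idx[:n_hold], idx[n_hold:]
    if len(train) < 2:
        raise ValueError("too few points for a held-out diagnostic")
    surr = train_surrogate(inputs[train], distances[train], restarts=2, seed=seed)
    mean, sd = surr.predict_batch(inputs[hold])
    z = (distances[hold] - mean) / np.maximum(sd, SD_FLOOR)
    frac = float(np.mean(np.abs(z) > z_limit))
    return {
        "n_holdout": int(n_hold),
        "frac_large_z": frac,
        "flagged": bool(frac > flag_frac),
        "max_abs_z": float(np.max(np.abs(z))),
    }


def save_surrogate(surr: DistanceSurrogate, path: str | Path) -> Path:
    """Versioned archive (inputs, targets, hyperparameters); retraining-free
    reload via refit with fixed hyperparameters."""
    path = Path(path)
    payload = {
        "schema_version": 1,
        "inputs": surr.inputs.tolist(),
        "targets": surr.targets.tolist(),
        "hyperparams": {
            "l": surr.hyperparams.l,
            "alpha": surr.hyperparams.alpha,
            "gamma_noise": surr.hyperparams.gamma_noise,
        },
        "log_marginal_likelihood": surr.log_marginal_likelihood,
    }
    path.write_text(json.dumps(payload))
    return path


def load_surrogate(path: str | Path) -> DistanceSurrogate:
    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != 1:
        raise ValueError("unsupported surrogate archive version")
    hp = KernelHyperparams(**d["hyperparams"])
    return train_surrogate(
        np.asarray(d["inputs"]),
        np.asarray(d["targets"]),
        optimize=False,
        init=hp,
    )
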