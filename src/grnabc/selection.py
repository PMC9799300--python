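"""Summary-statistic selection by approximate sufficiency (AS).

A statistic set S is approximately sufficient when adding any further
candidate no longer changes the approximate posterior.  The selection walk
therefore shuffles the candidate pool, tentatively adds one candidate at a
time, and keeps it only when the marginal posteriors with and without it
differ materially (the supremum binwise log posterior ratio exceeds a
threshold).  Because the walk order matters, the procedure is repeated with
fresh shuffles and the per-candidate selection frequency is reported; the
most frequently selected statistics form the chosen subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import PriorSpec
from .features import candidate_pool, ensemble_feature_vector


@dataclass(frozen=True)
class StatSelection:
    frequencies: dict
    n_repeats: int
    chosen: tuple
    accepted_sets: tuple

    def __post_init__(self) -> None:
        for f in self.frequencies.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("selection frequencies must lie in [0, 1]")


class ReferenceTableBackend:
    """Cheap posterior estimates from a precomputed simulation table.

    Given ensembles (or feature vectors) simulated at known parameter
    points, the posterior for a feature subset is the set of table points
    whose (per-feature standardised) L2 feature distance to the observed
    vector falls in the closest accept_frac fraction — plain rejection ABC
    against a reference table, which costs only array slicing per subset.
    """

    def __init__(self, observed_vector, thetas, table_vectors, accept_frac=0.2):
        self.keys = sorted(observed_vector)
        self.obs = np.array([observed_vector[k] for k in self.keys])
        self.thetas = np.asarray(thetas, dtype=float)
        self.table = np.array(
            [[vec[k] for k in self.keys] for vec in table_vectors]
        )
        scale = self.table.std(axis=0)
        self.scale = np.where(scale > 0, scale, 1.0)
        self.accept_frac = accept_frac

    @classmethod
    def from_ensembles(cls, observed, ensembles, names=None, accept_frac=0.2):
        keys = None
        vecs = []
        thetas = []
        from .features import FEATURE_NAMES

        names = names or FEATURE_NAMES
        for ens in ensembles:
            vecs.append(ensemble_feature_vector(ens, names))
            thetas.append((ens.D, ens.chi))
        return cls(ensemble_feature_vector(observed, names), thetas, vecs, accept_frac)

    def __call__(self, feature_keys) -> np.ndarray:
        """Posterior samples (n, 2) of (D, chi) given the feature subset."""
        if not feature_keys:
            return self.thetas
        idx = [self.keys.index(k) for k in feature_keys]
        z = (self.table[:, idx] - self.obs[idx]) / self.scale[idx]
        d = np.sqrt((z**2).sum(axis=1))
        n_accept = max(2, int(math.ceil(self.accept_frac * len(d))))
        keep = np.argsort(d, kind="stable")[:n_accept]
        return self.thetas[keep]


def _marginal_log_histograms(samples: np.ndarray, prior: PriorSpec, n_bins: int):
    lb = prior.log_bounds()
    logs = np.log10(samples)
    hists = []
    for axis in range(2):
        h, _ = np.histogram(logs[:, axis], bins=n_bins, range=tuple(lb[axis]))
        p = (h + 1.0) / (h.sum() + n_bins)  # pseudo-count regularised
        hists.append(np.log(p))
    return hists


def posterior_shift(
    samples_a: np.ndarray,
    samples_b: np.ndarray,
    prior: PriorSpec,
    n_bins: int = 20,
) -> float:
    """Supremum binwise absolute log posterior-density ratio between two
    sample sets, over both log-parameter marginals."""
    ha = _marginal_log_histograms(samples_a, prior, n_bins)
    hb = _marginal_log_histograms(samples_b, prior, n_bins)
    return float(max(np.max(np.abs(a - b)) for a, b in zip(ha, hb)))


def as_select(
    pool,
    backend,
    n_repeats: int = 20,
    seed: int = 0,
    threshold: float = math.log(4.0),
    n_bins: int = 20,
    top_k: int = 6,
    prior: PriorSpec | None = None,
    on_error: str = "continue",
) -> StatSelection:
    """Approximate-sufficiency selection over a candidate pool.

    pool: candidate feature keys (any hashables the backend accepts).
    backend: callable(subset) -> posterior samples (n, 2) of (D, chi); the
    empty subset must return the unconditioned (prior-level) samples.

    A candidate is kept when the supremum binwise log posterior-ratio it
    induces exceeds both the fixed threshold and the shift produced by pure
    resampling noise of the current posterior (bootstrap gate), so finite-
    sample histogram noise does not masquerade as information.
    """
    if not pool:
        raise ValueError("candidate pool must be non-empty")
    prior = prior or PriorSpec()
    rng = np.random.default_rng(seed)
    counts = {key: 0 for key in pool}
    accepted_sets = []
    done_repeats = 0
    for _rep in range(n_repeats):
        order = list(pool)
        rng.shuffle(order)
        try:
            selected: list = []
            post = backend(selected)
            for cand in order:
                post_new = backend(selected + [cand])
                score = posterior_shift(post, post_new, prior, n_bins)
                noise_floor = max(
                    posterior_shift(
                        post,
                        post[rng.integers(0, len(post), size=len(post_new))],
                        prior,
                        n_bins,
                    )
                    for _ in range(3)
                )
                if score > max(threshold, noise_floor):
                    selected.append(cand)
                    post = post_new
        except Exception:
            if on_error == "raise":
                raise
            continue  # a failed repeat is skipped; selection continues
        done_repeats += 1
        accepted_sets.append(tuple(selected))
        for key in selected:
            counts[key] += 1
    if done_repeats == 0:
        raise RuntimeError("every selection repeat failed")
    freqs = {key: c / done_repeats for key, c in counts.items()}
    ranked = sorted(pool, key=lambda k: (-freqs[k], str(k)))
    return StatSelection(
        frequencies=freqs,
        n_repeats=done_repeats,
        chosen=tuple(ranked[:top_k]),
        accepted_sets=tuple(accepted_sets),
    )
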