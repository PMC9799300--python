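"""Time-series summary statistics: the 18-feature candidate pool.

Conventions (documented because several features admit variants):

* standard deviation is the population value (divide by N);
* skewness and kurtosis are the population (biased) moment ratios, kurtosis
  the excess value (normal -> 0);
* "longest strike" runs use strict inequality against the mean;
* location features are occurrence indices normalised by the series length,
  "first" as index/N and "last" as (index+1)/N, so values lie in (0, 1].
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datasets import TrajectoryEnsemble

#: Canonical candidate pool, per species.
FEATURE_NAMES = (
    "sum_values",
    "abs_energy",
    "mean_abs_change",
    "mean_change",
    "median",
    "mean",
    "length",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "longest_strike_below_mean",
    "longest_strike_above_mean",
    "last_location_of_maximum",
    "first_location_of_maximum",
    "last_location_of_minimum",
    "first_location_of_minimum",
    "maximum",
    "minimum",
)

#: The four statistics of the hand-picked ("naive") distance.
NAIVE_STATS = ("mean", "minimum", "maximum", "standard_deviation")

#: The selected ("optimized") set reported for this system.  The spread
#: statistic is kept under the pool's standard_deviation name (the monotone
#: equivalent of the variance).
OPTIMIZED_STATS = (
    "longest_strike_below_mean",
    "longest_strike_above_mean",
    "mean_abs_change",
    "maximum",
    "minimum",
    "standard_deviation",
)

_CHANGE_FEATURES = {"mean_abs_change", "mean_change"}


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for hit in mask:
        run = run + 1 if hit else 0
        if run > best:
            best = run
    return best


def compute_feature(series, name: str) -> float:
    """Evaluate one named feature on a 1-d series."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("series must be 1-d and non-empty")
    n = len(x)
    if name in _CHANGE_FEATURES and n < 2:
        raise ValueError(f"{name} needs at least 2 samples")
    if name == "sum_values":
        return float(np.sum(x))
    if name == "abs_energy":
        return float(np.sum(x * x))
    if name == "mean_abs_change":
        return float(np.mean(np.abs(np.diff(x))))
    if name == "mean_change":
        return float((x[-1] - x[0]) / (n - 1))
    if name == "median":
        return float(np.median(x))
    if name == "mean":
        return float(np.mean(x))
    if name == "length":
        return float(n)
    if name == "standard_deviation":
        return float(np.std(x))
    if name == "skewness":
        if np.ptp(x) == 0:
            return 0.0  # constant series: define the moment ratio as 0
        return float(stats.skew(x, bias=True))
    if name == "kurtosis":
        if np.ptp(x) == 0:
            return 0.0
        return float(stats.kurtosis(x, bias=True))
    if name == "longest_strike_below_mean":
        return float(_longest_run(x < np.mean(x)))
    if name == "longest_strike_above_mean":
        return float(_longest_run(x > np.mean(x)))
    if name == "last_location_of_maximum":
        return float((n - 1 - int(np.argmax(x[::-1])) + 1) / n)
    if name == "first_location_of_maximum":
        return float(int(np.argmax(x)) / n)
    if name == "last_location_of_minimum":
        return float((n - 1 - int(np.argmin(x[::-1])) + 1) / n)
    if name == "first_location_of_minimum":
        return float(int(np.argmin(x)) / n)
    if name == "maximum":
        return float(np.max(x))
    if name == "minimum":
        return float(np.min(x))
    raise ValueError(f"unknown feature {name!r}")


def candidate_pool(species=("mRNA", "P")) -> list[tuple[str, str]]:
    """(species, feature) keys of the full candidate pool."""
    return [(sp, name) for sp in species for name in FEATURE_NAMES]


def per_trajectory_features(
    ens: TrajectoryEnsemble, names=FEATURE_NAMES
) -> dict[tuple[str, str], np.ndarray]:
    """Feature values per trajectory: key (species, feature) -> (n_traj,)."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for si, sp in enumerate(ens.species):
        series = ens.counts[:, :, si]
        for name in names:
            out[(sp, name)] = np.array(
                [compute_feature(series[t], name) for t in range(ens.n_trajectories)]
            )
    return out


def ensemble_feature_vector(
    ens: TrajectoryEnsemble, names=FEATURE_NAMES
) -> dict[tuple[str, str], float]:
    """Per-trajectory features averaged over trajectories (one value per
    (species, feature) key) — the summary-statistic vector of an ensemble."""
    per_traj = per_trajectory_features(ens, names)
    vec = {key: float(np.mean(vals)) for key, vals in per_traj.items()}
    for value in vec.values():
        if not np.isfinite(value):
            raise ValueError("non-finite feature value in ensemble vector")
    return vec


def naive_stat_vector(ens: TrajectoryEnsemble) -> dict[tuple[str, str], float]:
    """The hand-picked 4-statistic vector (mean, min, max, sd) per species,
    averaged over trajectories."""
    return ensemble_feature_vector(ens, NAIVE_STATS)
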