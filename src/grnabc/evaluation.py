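"""Posterior error metrics against known truth, error maps, boxen summaries.

The headline metric is the expected log-error

    eps = E_posterior[ || log10(theta_hat) - log10(theta_true) ||_2 ],

the posterior-weighted mean Euclidean distance in orders of magnitude.  It
grows with both bias and posterior width, so a wide posterior centred on
the truth still scores worse than a tight one.  An RMSE variant in linear
parameter units is provided for sensitivity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ParameterGrid
from .inference import Posterior

STATUS_OK = "ok"
STATUS_FAILED = "failed"


def expected_log_error(posterior: Posterior, theta_true) -> float:
    """Weighted mean of ||log10(theta_hat) - log10(theta_true)||_2."""
    w = posterior.weights
    if len(w) == 0 or not np.isfinite(w).all() or w.sum() <= 0:
        raise ValueError("posterior weights empty, zero or non-finite")
    diff = posterior.log_samples - np.log10(np.asarray(theta_true, float))
    norms = np.linalg.norm(diff, axis=1)
    return float(w @ norms)


def rmse_error(posterior: Posterior, theta_true, log_space: bool = False) -> float:
    """Root weighted mean squared Euclidean error.

    Linear parameter units by default; log_space=True measures in log10
    units instead (sensitivity variant).
    """
    w = posterior.weights
    if len(w) == 0 or not np.isfinite(w).all() or w.sum() <= 0:
        raise ValueError("posterior weights empty, zero or non-finite")
    if log_space:
        diff = posterior.log_samples - np.log10(np.asarray(theta_true, float))
    else:
        diff = posterior.samples - np.asarray(theta_true, float)
    sq = (diff**2).sum(axis=1)
    return float(np.sqrt(w @ sq))


@dataclass(frozen=True)
class ErrorMap:
    """Per-grid-point scalar error for one (model, metric, scenario) setup."""

    grid: ParameterGrid
    values: np.ndarray  # (n_points,) error; NaN where failed
    status: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.grid) or len(self.status) != len(self.grid):
            raise ValueError("one value and status required per grid point")
        ok = np.array([s == STATUS_OK for s in self.status])
        vals = self.values[ok]
        if len(vals) and not (np.isfinite(vals).all() and (vals >= 0).all()):
            raise ValueError("ok-status errors must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        rows = self.grid.manifest_rows()
        return pd.DataFrame(
            {
                "D": [r["D"] for r in rows],
                "chi": [r["chi"] for r in rows],
                "error": self.values,
                "status": list(self.status),
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta_path = path.with_suffix(".meta.json")
        meta = dict(self.metadata)
        meta.update({"n_D": self.grid.n_D, "n_chi": self.grid.n_chi})
        meta_path.write_text(json.dumps(meta))
        return path

    @classmethod
    def from_csv(cls, path: str | Path, grid: ParameterGrid) -> "ErrorMap":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            grid=grid,
            values=df["error"].to_numpy(),
            status=tuple(df["status"]),
            metadata=metadata,
        )

    def ok_values(self) -> np.ndarray:
        return self.values[[s == STATUS_OK for s in self.status]]


def build_error_map(
    posteriors: dict[int, Posterior | None],
    grid: ParameterGrid,
    error_metric=expected_log_error,
    metadata: dict | None = None,
) -> ErrorMap:
    """Apply the error metric per grid point; missing or failed inferences
    are flagged (never rendered as zero error)."""
    values = np.full(len(grid), np.nan)
    status = []
    for i, (D, chi) in enumerate(grid.points):
        post = posteriors.get(i)
        if post is None:
            status.append(STATUS_FAILED)
            continue
        values[i] = error_metric(post, (D, chi))
        status.append(STATUS_OK)
    return ErrorMap(grid=grid, values=values, status=tuple(status), metadata=metadata or {})


@dataclass(frozen=True)
class BoxenSummary:
    """Quartiles plus successive 2^-n tail quantiles (letter-value style)."""

    levels: tuple[float, ...]
    quantiles: tuple[float, ...]
    median: float
    n: int

    def __post_init__(self) -> None:
        q = np.asarray(self.quantiles)
        if (np.diff(q) < -1e-12).any():
            raise ValueError("quantile sequence must be monotone")


def boxen_levels(n: int) -> tuple[float, ...]:
    """Quantile levels {2^-k, 1-2^-k} down to the one-observation floor."""
    if n < 8:
        raise ValueError("need at least 8 values")
    levels = {0.25, 0.5, 0.75}
    k = 3
    while n * 2.0**-k >= 1.0:
        levels.add(2.0**-k)
        levels.add(1.0 - 2.0**-k)
        k += 1
    return tuple(sorted(levels))


def boxen_summary(errors) -> BoxenSummary:
    x = np.asarray(errors, dtype=float)
    x = x[np.isfinite(x)]
    levels = boxen_levels(len(x))
    q = np.quantile(x, levels)  # linear interpolation between order stats
    return BoxenSummary(
        levels=levels,
        quantiles=tuple(float(v) for v in q),
        median=float(np.median(x)),
        n=len(x),
    )


def plot_error_map(emap: ErrorMap, path: str | Path, title: str | None = None):
    """Heatmap of the error surface, log-scaled axes (D on y, chi on x)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = emap.values.reshape(emap.grid.n_D, emap.grid.n_chi)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(vals, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(emap.grid.n_chi))
    ax.set_xticklabels([f"{c:.3g}" for c in emap.grid.chi_values], rotation=90, fontsize=6)
    ax.set_yticks(range(emap.grid.n_D))
    ax.set_yticklabels([f"{d:.3g}" for d in emap.grid.D_values], fontsize=6)
    ax.set_xlabel("chi")
    ax.set_ylabel("D (um^2/min)")
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="expected log-error")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
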