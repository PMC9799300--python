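"""Trajectory ensembles, on-disk schema, grid generation, data scenarios.

An ensemble holds replicate (mRNA, P) time series simulated at one
(D, chi) point with one model.  The study's data scenarios are expressed as
operators on ensembles: coarsening the time axis, subsampling replicate
trajectories, and restricting the observed species.

On-disk formats: a versioned JSON schema for single ensembles and an HDF5
mirror (one group per grid point) for whole ground-truth grids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .core import ParameterGrid, make_parameters
from .simulators import SimulationConfig, simulate

SCHEMA_VERSION = 1
SPECIES = ("mRNA", "P")


class SchemaError(ValueError):
    """Raised when an on-disk ensemble does not match the expected schema."""


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Replicate trajectories at one parameter point for one model.

    counts has shape (n_traj, n_time, n_species); species names the last
    axis.  seeds records the per-trajectory simulator seeds (the manifest).
    """

    model: str
    D: float
    chi: float
    times: np.ndarray
    species: tuple[str, ...]
    counts: np.ndarray
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError("counts must be (n_traj, n_time, n_species)")
        n_traj, n_time, n_sp = self.counts.shape
        if n_traj < 1:
            raise ValueError("ensemble needs at least one trajectory")
        if n_time != len(self.times):
            raise ValueError("time axis mismatch")
        if n_sp != len(self.species):
            raise ValueError("species axis mismatch")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_trajectories(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"species {name!r} not in ensemble {self.species}") from None

    def __eq__(self, other) -> bool:  # value equality incl. arrays
        if not isinstance(other, TrajectoryEnsemble):
            return NotImplemented
        return (
            self.model == other.model
            and self.D == other.D
            and self.chi == other.chi
            and self.species == other.species
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """A data-availability scenario applied uniformly to every ensemble."""

    n_time_samples: int | None = None  # None = keep all
    n_trajectories: int | None = None
    species: str = "both"  # both | protein_only | mrna_only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in ("both", "protein_only", "mrna_only"):
            raise ValueError(f"unknown species selection {self.species!r}")

    def apply(self, ens: TrajectoryEnsemble) -> TrajectoryEnsemble:
        out = ens
        if self.n_time_samples is not None and self.n_time_samples != out.n_samples:
            out = coarsen_time(out, self.n_time_samples)
        if self.n_trajectories is not None and self.n_trajectories != out.n_trajectories:
            out = subsample_trajectories(out, self.n_trajectories, self.seed)
        if self.species != "both":
            out = select_species(out, self.species)
        return out


# ---------------------------------------------------------------------------
# Scenario operators
# ---------------------------------------------------------------------------

def coarsen_indices(n_source: int, n_keep: int) -> np.ndarray:
    """Indices kept when thinning n_source samples to n_keep: rounded
    linspace over [0, n_source-1], so the first and last sample survive."""
    return np.round(np.linspace(0, n_source - 1, n_keep)).astype(int)


def coarsen_time(ens: TrajectoryEnsemble, n: int) -> TrajectoryEnsemble:
    """Keep n time samples (endpoints always included)."""
    if not (1 <= n <= ens.n_samples):
        raise ValueError(f"cannot keep {n} of {ens.n_samples} samples")
    idx = coarsen_indices(ens.n_samples, n)
    return replace(ens, times=ens.times[idx], counts=ens.counts[:, idx, :])


def subsample_trajectories(ens: TrajectoryEnsemble, k: int, seed: int) -> TrajectoryEnsemble:
    """Draw k trajectories without replacement (seeded)."""
    if not (1 <= k <= ens.n_trajectories):
        raise ValueError(f"cannot draw {k} of {ens.n_trajectories} trajectories")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(ens.n_trajectories, size=k, replace=False))
    seeds = tuple(ens.seeds[i] for i in idx) if ens.seeds else ()
    return replace(ens, counts=ens.counts[idx], seeds=seeds)


def select_species(ens: TrajectoryEnsemble, which: str) -> TrajectoryEnsemble:
    """Restrict the species axis: 'both', 'protein_only' or 'mrna_only'."""
    if which == "both":
        return ens
    name = {"protein_only": "P", "mrna_only": "mRNA"}.get(which)
    if name is None:
        raise ValueError(f"unknown species selection {which!r}")
    i = ens.species_index(name)
    return replace(ens, species=(name,), counts=ens.counts[:, :, i : i + 1])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def ensemble_to_dict(ens: TrajectoryEnsemble) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "model": ens.model,
        "D": ens.D,
        "chi": ens.chi,
        "times": ens.times.tolist(),
        "species": list(ens.species),
        "seeds": list(ens.seeds),
        "trajectories": ens.counts.tolist(),
    }


def ensemble_from_dict(d: dict) -> TrajectoryEnsemble:
    try:
        version = d["schema_version"]
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version {version} unsupported (expected {SCHEMA_VERSION})"
            )
        return TrajectoryEnsemble(
            model=d["model"],
            D=float(d["D"]),
            chi=float(d["chi"]),
            times=np.asarray(d["times"], dtype=float),
            species=tuple(d["species"]),
            counts=np.asarray(d["trajectories"], dtype=np.int64),
            seeds=tuple(int(s) for s in d.get("seeds", ())),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, SchemaError):
            raise
        raise SchemaError(f"malformed ensemble payload: {exc}") from exc


def save_ensemble(ens: TrajectoryEnsemble, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(ensemble_to_dict(ens)))
    return path


def load_ensemble(path: str | Path) -> TrajectoryEnsemble:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not a valid ensemble JSON file: {exc}") from exc
    return ensemble_from_dict(payload)


# ---------------------------------------------------------------------------
# Ground-truth grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthGrid:
    """One ensemble per grid point, all from the same generator model."""

    grid: ParameterGrid
    ensembles: tuple[TrajectoryEnsemble, ...]
    model: str

    def __post_init__(self) -> None:
        if len(self.ensembles) != len(self.grid):
            raise ValueError("one ensemble required per grid point")

    def __getitem__(self, i: int) -> TrajectoryEnsemble:
        return self.ensembles[i]

    def apply_scenario(self, scenario: ScenarioSpec) -> "GroundTruthGrid":
        return GroundTruthGrid(
            self.grid, tuple(scenario.apply(e) for e in self.ensembles), self.model
        )


def generate_ensemble(
    model: str,
    D: float,
    chi: float,
    n_traj: int,
    config: SimulationConfig,
    seeds: list[int] | None = None,
) -> TrajectoryEnsemble:
    """Simulate n_traj independent replicates at one parameter point."""
    params = make_parameters(chi, D)
    if seeds is None:
        root = np.random.SeedSequence(config.seed)
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_traj)]
    counts = []
    for s in seeds:
        traj = simulate(model, params, replace(config, seed=s))
        counts.append(traj.counts)
    times = config.sample_times()
    return TrajectoryEnsemble(
        model=model.upper(),
        D=D,
        chi=chi,
        times=times,
        species=SPECIES,
        counts=np.stack(counts),
        seeds=tuple(seeds),
    )


def generate_grid_data(
    grid: ParameterGrid,
    model: str,
    n_traj: int,
    config: SimulationConfig,
) -> GroundTruthGrid:
    """Simulate an ensemble at every grid point.

    Per-point, per-trajectory seeds are derived from config.seed through a
    splittable SeedSequence tree and recorded in each ensemble's manifest,
    so regeneration from the same config is bitwise reproducible.
    """
    root = np.random.SeedSequence(config.seed)
    point_seqs = root.spawn(len(grid))
    ensembles = []
    for (D, chi), seq in zip(grid.points, point_seqs):
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(n_traj)]
        ensembles.append(generate_ensemble(model, D, chi, n_traj, config, seeds=seeds))
    return GroundTruthGrid(grid, tuple(ensembles), model.upper())


def save_grid(gtg: GroundTruthGrid, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["model"] = gtg.model
        f.attrs["n_D"] = gtg.grid.n_D
        f.attrs["n_chi"] = gtg.grid.n_chi
        f.create_dataset("D_values", data=np.asarray(gtg.grid.D_values))
        f.create_dataset("chi_values", data=np.asarray(gtg.grid.chi_values))
        for i, ens in enumerate(gtg.ensembles):
            g = f.create_group(f"point_{i:04d}")
            g.attrs["D"] = ens.D
            g.attrs["chi"] = ens.chi
            g.attrs["model"] = ens.model
            g.attrs["species"] = ",".join(ens.species)
            g.create_dataset("times", data=ens.times)
            g.create_dataset("counts", data=ens.counts, compression="gzip")
            g.create_dataset("seeds", data=np.asarray(ens.seeds, dtype=np.int64))
    return path


def load_grid(path: str | Path) -> GroundTruthGrid:
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError("unsupported grid schema version")
        grid = ParameterGrid(
            int(f.attrs["n_D"]),
            int(f.attrs["n_chi"]),
            tuple(np.asarray(f["D_values"])),
            tuple(np.asarray(f["chi_values"])),
        )
        ensembles = []
        for i in range(len(grid)):
            g = f[f"point_{i:04d}"]
            ensembles.append(
                TrajectoryEnsemble(
                    model=str(g.attrs["model"]),
                    D=float(g.attrs["D"]),
                    chi=float(g.attrs["chi"]),
                    times=np.asarray(g["times"]),
                    species=tuple(str(g.attrs["species"]).split(",")),
                    counts=np.asarray(g["counts"], dtype=np.int64),
                    seeds=tuple(int(s) for s in np.asarray(g["seeds"])),
                )
            )
        return GroundTruthGrid(grid, tuple(ensembles), str(f.attrs["model"]))
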