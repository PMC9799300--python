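"""End-to-end orchestration: generate once, emulate distances, infer, map.

The workflow per setup (metric x data scenario):

1. simulate ground-truth ensembles at every grid point with the truth
   model, and simulated ensembles with each inference model (data are
   generated once and reused both as observed data and as surrogate
   training data);
2. for each observed grid point and inference model, compute the distance
   from the observed ensemble to every simulated ensemble, fit the GP
   surrogate over (log10 D, log10 chi), and run ABC-SMC against surrogate-
   sampled distances — no simulator calls during inference;
3. score each posterior against the known truth (expected log-error) and
   assemble per-model error maps.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ParameterGrid, PriorSpec, make_grid
from .datasets import (
    GroundTruthGrid,
    ScenarioSpec,
    TrajectoryEnsemble,
    generate_grid_data,
    load_grid,
    save_grid,
)
from .distances import DistanceMetricSpec, make_distance
from .evaluation import ErrorMap, build_error_map, expected_log_error, plot_error_map
from .inference import (
    InferenceFailure,
    Posterior,
    SMCConfig,
    run_inference,
    surrogate_distance_fn,
)
from .surrogate import holdout_diagnostic, save_surrogate, train_surrogate


@dataclass(frozen=True)
class PipelineConfig:
    n_D: int = 4
    n_chi: int = 4
    truth_model: str = "CBM"
    inference_models: tuple[str, ...] = ("WMM", "CBM")
    metrics: tuple[DistanceMetricSpec, ...] = (DistanceMetricSpec("kolmogorov"),)
    scenarios: tuple[ScenarioSpec, ...] = (ScenarioSpec(),)
    n_traj: int = 8
    n_samples: int = 20
    dt_sample: float = 5.0
    t_burn: float = 200.0
    dt_bd: float = 0.01
    smc: SMCConfig = field(default_factory=SMCConfig)
    seed: int = 0
    replicate_split: bool = True  # two half-ensemble distances per point
    output_root: str = "runs"

    def grid(self) -> ParameterGrid:
        return make_grid(self.n_D, self.n_chi)

    def sim_config(self, seed: int = 0):
        from .simulators import SimulationConfig

        return SimulationConfig(
            t_burn=self.t_burn,
            n_samples=self.n_samples,
            dt_sample=self.dt_sample,
            dt_bd=self.dt_bd,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate(self) -> None:
        from .simulators import MODELS

        if self.truth_model.upper() not in MODELS:
            raise ValueError(f"unknown truth model {self.truth_model}")
        for m in self.inference_models:
            if m.upper() not in MODELS:
                raise ValueError(f"unknown inference model {m}")
        if not self.metrics or not self.scenarios:
            raise ValueError("need at least one metric and one scenario")
        for sc in self.scenarios:
            if sc.n_time_samples is not None and sc.n_time_samples > self.n_samples:
                raise ValueError("scenario requests more time samples than simulated")
            if sc.n_trajectories is not None and sc.n_trajectories > self.n_traj:
                raise ValueError("scenario requests more trajectories than simulated")
        self.grid()
        self.sim_config()


@dataclass(frozen=True)
class Task:
    setup: int  # index into metrics x scenarios
    metric: str
    scenario_index: int
    point_index: int
    D: float
    chi: float
    model: str
    seed: int

    def key(self) -> str:
        return (
            f"setup{self.setup}_pt{self.point_index:04d}_{self.model.lower()}"
        )


@dataclass(frozen=True)
class TaskPlan:
    tasks: tuple[Task, ...]
    n_setups: int

    @property
    def tasks_per_setup(self) -> int:
        return len(self.tasks) // self.n_setups

    def content_hash(self) -> str:
        blob = json.dumps([asdict(t) for t in self.tasks], sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


def plan_setup(config: PipelineConfig) -> TaskPlan:
    """Enumerate one inference task per (grid point, inference model) for
    every setup (metric x scenario), with deterministic ordering/seeding."""
    config.validate()
    grid = config.grid()
    tasks = []
    setups = [(m, si) for m in config.metrics for si in range(len(config.scenarios))]
    for s_idx, (metric, sc_idx) in enumerate(setups):
        for p_idx, (D, chi) in enumerate(grid.points):
            for m_idx, model in enumerate(config.inference_models):
                tasks.append(
                    Task(
                        setup=s_idx,
                        metric=metric.name,
                        scenario_index=sc_idx,
                        point_index=p_idx,
                        D=D,
                        chi=chi,
                        model=model.upper(),
                        seed=_derive_seed(config.seed, 7001, s_idx, p_idx, m_idx),
                    )
                )
    return TaskPlan(tuple(tasks), n_setups=len(setups))


def _split_halves(ens: TrajectoryEnsemble) -> list[TrajectoryEnsemble]:
    """Two disjoint half-ensembles (replicate distance evaluations)."""
    n = ens.n_trajectories
    if n < 2:
        return [ens]
    h = n // 2
    return [
        replace(ens, counts=ens.counts[:h], seeds=ens.seeds[:h] if ens.seeds else ()),
        replace(ens, counts=ens.counts[h : 2 * h], seeds=ens.seeds[h : 2 * h] if ens.seeds else ()),
    ]


def surrogate_training_set(
    observed: TrajectoryEnsemble,
    simulated: GroundTruthGrid,
    metric: DistanceMetricSpec,
    replicate_split: bool = True,
):
    """Distance targets for the surrogate: observed vs every simulated grid
    ensemble, optionally doubled by splitting each ensemble into halves
    (two stochastic replicates per grid point)."""
    dist = make_distance(metric)
    inputs = []
    targets = []
    for ens in simulated.ensembles:
        pieces = _split_halves(ens) if replicate_split else [ens]
        for piece in pieces:
            inputs.append(np.log10([ens.D, ens.chi]))
            targets.append(dist(observed, piece))
    return np.array(inputs), np.array(targets)


def run_task(
    task: Task,
    observed: TrajectoryEnsemble,
    simulated: GroundTruthGrid,
    metric: DistanceMetricSpec,
    scenario: ScenarioSpec,
    smc: SMCConfig,
    replicate_split: bool = True,
) -> tuple[Posterior, dict]:
    """Train the surrogate for one observed point and run ABC-SMC on it."""
    from . import simulators

    obs_sc = scenario.apply(observed)
    sim_sc = simulated.apply_scenario(scenario)
    X, y = surrogate_training_set(obs_sc, sim_sc, metric, replicate_split)
    surr = train_surrogate(X, y, restarts=3, seed=task.seed)
    calls_before = simulators.simulator_call_count()
    post = run_inference(
        obs_sc,
        surrogate_distance_fn(surr),
        smc,
        seed=task.seed,
        provenance={
            "metric": metric.name,
            "model": task.model,
            "task": task.key(),
        },
    )
    info = {
        "task": task.key(),
        "surrogate_lml": surr.log_marginal_likelihood,
        "hyperparams": asdict(surr.hyperparams),
        "simulator_calls_during_smc": simulators.simulator_call_count() - calls_before,
        "acceptance_rates": list(post.acceptance_rates),
        "epsilons": list(post.epsilons),
    }
    return post, info


def save_posterior(post: Posterior, path: Path) -> None:
    df = pd.DataFrame(
        {"D": post.samples[:, 0], "chi": post.samples[:, 1], "weight": post.weights}
    )
    df.to_csv(path, index=False)
    path.with_suffix(".provenance.json").write_text(json.dumps(post.provenance))


def load_posterior(path: Path) -> Posterior:
    df = pd.read_csv(path)
    prov_path = path.with_suffix(".provenance.json")
    prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    w = df["weight"].to_numpy()
    return Posterior(
        samples=df[["D", "chi"]].to_numpy(), weights=w / w.sum(), provenance=prov
    )


def run_pipeline(config: PipelineConfig, progress: bool = False) -> dict:
    """Execute the full workflow; returns a summary dict.

    Layout under <output_root>/run_<config hash>/: datasets/ (HDF5 grids),
    surrogates/, posteriors/ (CSV + provenance), maps/ (CSV + PNG),
    manifest.json, log.jsonl.  Completed tasks (existing posterior files)
    are skipped, so an interrupted run resumes to identical outputs.
    """
    config.validate()
    run_dir = Path(config.output_root) / f"run_{config.content_hash()}"
    for sub in ("datasets", "surrogates", "posteriors", "maps"):
        (run_dir / sub).mkdir(parents=True, exist_ok=True)
    log_path = run_dir / "log.jsonl"
    grid = config.grid()

    def _grid_data(model: str) -> GroundTruthGrid:
        path = run_dir / "datasets" / f"grid_{model.lower()}.h5"
        if path.exists():
            return load_grid(path)
        from .simulators import MODELS

        data = generate_grid_data(
            grid,
            model,
            config.n_traj,
            config.sim_config(seed=_derive_seed(config.seed, 11, MODELS.index(model))),
        )
        save_grid(data, path)
        return data

    truth = _grid_data(config.truth_model.upper())
    sims = {m.upper(): _grid_data(m.upper()) for m in config.inference_models}
    if config.truth_model.upper() in sims:
        pass  # same dataset reused as observed data and training data

    plan = plan_setup(config)
    setups = [
        (metric, scenario)
        for metric in config.metrics
        for scenario in config.scenarios
    ]
    posteriors: dict[tuple[int, str], dict[int, Posterior | None]] = {}
    failures = 0
    with log_path.open("a") as log:
        for task in plan.tasks:
            metric, scenario = setups[task.setup]
            key = (task.setup, task.model)
            posteriors.setdefault(key, {})
            post_path = run_dir / "posteriors" / f"{task.key()}.csv"
            if post_path.exists():
                posteriors[key][task.point_index] = load_posterior(post_path)
                continue
            t0 = time.time()
            try:
                post, info = run_task(
                    task,
                    truth[task.point_index],
                    sims[task.model],
                    metric,
                    scenario,
                    config.smc,
                    config.replicate_split,
                )
            except InferenceFailure as exc:
                posteriors[key][task.point_index] = None
                failures += 1
                log.write(
                    json.dumps(
                        {"task": task.key(), "status": "failed", "error": str(exc)}
                    )
                    + "\n"
                )
                continue
            save_posterior(post, post_path)
            # re-read the persisted form so fresh and resumed runs are
            # byte-identical downstream
            posteriors[key][task.point_index] = load_posterior(post_path)
            info.update({"status": "ok", "duration_s": round(time.time() - t0, 3)})
            log.write(json.dumps(info) + "\n")
            if progress:
                print(f"done {task.key()} in {info['duration_s']}s")

    maps = {}
    medians = {}
    for (s_idx, model), posts in posteriors.items():
        metric, scenario = setups[s_idx]
        meta = {
            "model": model,
            "metric": metric.name,
            "scenario": asdict(scenario),
            "truth_model": config.truth_model.upper(),
            "config_hash": config.content_hash(),
        }
        emap = build_error_map(posts, grid, expected_log_error, meta)
        name = f"setup{s_idx}_{model.lower()}"
        emap.to_csv(run_dir / "maps" / f"{name}.csv")
        plot_error_map(
            emap,
            run_dir / "maps" / f"{name}.png",
            title=f"{model} | {metric.name}",
        )
        maps[name] = emap
        ok = emap.ok_values()
        medians[name] = float(np.median(ok)) if len(ok) else float("nan")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "plan_hash": plan.content_hash(),
        "tasks": len(plan.tasks),
        "tasks_per_setup": plan.tasks_per_setup,
        "failures": failures,
        "median_expected_log_error": medians,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "run_dir": run_dir,
        "maps": maps,
        "medians": medians,
        "manifest": manifest,
        "failures": failures,
    }


def make_fixture_config(scale: str = "desk", seed: int = 0, output_root: str = "runs") -> PipelineConfig:
    """Ready-made configurations: 'smoke' (minutes, one model), 'desk'
    (scaled-down model-fidelity comparison) and 'full' (the original study
    dimensions — hundreds of core-hours; emit only for cluster use)."""
    if scale == "smoke":
        return PipelineConfig(
            n_D=3,
            n_chi=3,
            truth_model="WMM",
            inference_models=("WMM",),
            metrics=(DistanceMetricSpec("kolmogorov"),),
            n_traj=4,
            n_samples=10,
            dt_sample=5.0,
            t_burn=150.0,
            smc=SMCConfig(population=100, n_generations=4, pilot=400),
            seed=seed,
            output_root=output_root,
        )
    if scale == "desk":
        return PipelineConfig(
            n_D=4,
            n_chi=4,
            truth_model="CBM",
            inference_models=("WMM", "CBM"),
            metrics=(DistanceMetricSpec("kolmogorov"),),
            n_traj=8,
            n_samples=20,
            dt_sample=5.0,
            t_burn=200.0,
            smc=SMCConfig(population=200, n_generations=8),
            seed=seed,
            output_root=output_root,
        )
    if scale == "full":
        return PipelineConfig(
            n_D=16,
            n_chi=16,
            truth_model="SPATIAL",
            inference_models=("WMM", "CBM", "SPATIAL"),
            metrics=(
                DistanceMetricSpec("naive_stats"),
                DistanceMetricSpec("optimized_stats"),
                DistanceMetricSpec("kolmogorov"),
            ),
            n_traj=64,
            n_samples=100,
            dt_sample=10.0,
            t_burn=500.0,
            smc=SMCConfig(population=200, n_generations=8),
            seed=seed,
            output_root=output_root,
        )
    raise ValueError(f"unknown scale {scale!r}")


def config_from_file(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from YAML or JSON."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    metrics = tuple(
        DistanceMetricSpec(**m) if isinstance(m, dict) else DistanceMetricSpec(m)
        for m in raw.pop("metrics", ["kolmogorov"])
    )
    scenarios = tuple(
        ScenarioSpec(**s) for s in raw.pop("scenarios", [{}])
    )
    smc = SMCConfig(**raw.pop("smc", {}))
    if "inference_models" in raw:
        raw["inference_models"] = tuple(raw["inference_models"])
    return PipelineConfig(metrics=metrics, scenarios=scenarios, smc=smc, **raw)
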