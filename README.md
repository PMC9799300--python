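# grnabc

Systematic, simulation-driven evaluation of likelihood-free (ABC) parameter
inference for a spatial stochastic model of negative-feedback gene
expression, made tractable on a desktop by Gaussian-process surrogates of
the ABC distance metric.

## The scientific problem

A self-repressing gene (a Hes1-like motif) is modelled with five reactions:

    G + P  <->  GP          binding k_a / unbinding k_d   (nucleus)
    G      ->   G + mRNA    transcription mu              (nucleus)
    mRNA   ->   mRNA + P    translation kappa             (cytoplasm)
    mRNA   ->   0           degradation gamma             (whole cell)
    P      ->   0           degradation gamma             (whole cell)

mRNA is transcribed in the nucleus, translated in the cytoplasm, and the
protein diffuses back to repress its own gene.  Two quantities are the
inference targets: the diffusion coefficient **D** and a dimensionless
reactivity multiplier **χ** that scales μ, κ and γ simultaneously
(base values μ=3, κ=1 min⁻¹, γ=0.04 min⁻¹ at χ=1; D=0.6 μm²·min⁻¹).
The prior is log-uniform, D ∈ [0.0039, 16] and χ ∈ [0.25, 16].

The same network is simulated at three fidelities, all sharing the same
physical constants (the gene–protein association uses the Collins–Kimball
diffusion-limited rate k_eff = k_a·k_D/(k_a + k_D), k_D = 4πσD):

* **WMM** — whole cell well mixed; exact Gillespie SSA.
* **CBM** — nucleus and cytoplasm each well mixed, coupled by
  first-passage hop rates (k_exit = 15D/r², k_entry from the closed-form
  shell mean-first-passage time); exact SSA.
* **SPATIAL** — Brownian-dynamics particle model: every molecule takes
  Gaussian steps of per-axis variance 2·D·Δt, reflects at the cell
  membrane, and the gene binds proteins entering a calibrated binding
  radius.

The question the pipeline answers: *for which regions of (D, χ) space, and
for which choice of simulator, distance metric and amount of data, does
ABC-SMC actually recover the truth?*  For every point of a log-spaced
(D, χ) grid, ground-truth ensembles are simulated once, distances between
the observed ensemble and ensembles simulated across the grid are fitted
with a Gaussian process over (log₁₀D, log₁₀χ) (rational-quadratic plus
white-noise kernel), and ABC-SMC then runs against stochastic
surrogate-sampled distances — zero simulator calls during inference.  Each
posterior is scored against the known truth with the **expected
log-error**

    ε = E_posterior[ ‖log₁₀(θ̂) − log₁₀(θ∘)‖₂ ],

which penalises both bias and posterior width, and the per-grid-point
errors form an error map.

Distance metrics provided: a naive 4-statistic L2 (mean, min, max, sd), an
optimized 6-statistic L2 (selected by approximate sufficiency from an
18-feature-per-species pool), the Kolmogorov distance on per-time-point
count distributions, and a Kolmogorov-on-statistics variant.  Data
scenarios: time-sample coarsening (100 → 12/6/3), trajectory subsampling
(64 → 4), and species restriction (mRNA-only / protein-only / both).

## Worked example

Run the smallest end-to-end configuration (3×3 grid, well-mixed truth,
4 trajectories × 10 samples per ensemble, Kolmogorov distance):

```python
from grnabc.pipeline import make_fixture_config, run_pipeline

cfg = make_fixture_config("smoke", seed=1, output_root="runs")
res = run_pipeline(cfg)
print(res["medians"])
```

which prints

```
{'setup0_wmm': 0.5886207539398672}
```

— the median expected log-error over the nine grid points when the
observed data are re-inferred with the same well-mixed model.  A value of
0.59 means the posterior mass sits, on average, about half an order of
magnitude from the true (D, χ).  The per-point error map written to
`runs/run_<hash>/maps/` shows where inference is easy and where it is not:

```
      D   chi    error
 0.0039  0.25 1.014876
 0.0039  2.00 0.523271
 0.0039 16.00 0.773327
 0.2498  0.25 0.481619
 0.2498  2.00 0.588621
 0.2498 16.00 1.354536
16.0000  0.25 0.573779
16.0000  2.00 0.481192
16.0000 16.00 0.997995
```

Errors are largest toward the fast-reaction corner (χ=16), where the
count distributions change little with D — those parameters are weakly
identifiable from this amount of data.

The same workflow is scriptable from the shell (`grnabc --help`):
`simulate`, `generate-data`, `train-surrogate`, `select-stats`, `infer`,
`evaluate`, `report`, and `run` (full pipeline from a YAML config or a
fixture scale; `--scale full` emits the original study dimensions — 16×16
grid, 64×100-sample ensembles, three models — which needs hundreds of
core-hours and is intended for cluster use).

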