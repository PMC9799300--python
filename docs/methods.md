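# Methods

## Model

A single gene at the centre of a spherical nucleus (radius r = 2.5 μm)
inside a spherical cell (R = 6 μm) represses its own expression: the free
gene transcribes mRNA at rate μ; mRNA is translated to protein at rate κ,
but only in the cytoplasm; protein binds the free gene at the bimolecular
rate k_a (nucleus) and unbinds at k_d; both species degrade at γ
everywhere.  Base rates (χ=1): μ = 3, κ = 1, k_d = 0.1, γ = 0.04 min⁻¹,
k_a = 10⁹ M⁻¹min⁻¹.  The inference coordinates are the diffusion
coefficient D and the reactivity multiplier χ, which scales μ, κ and γ
together (k_d is not scaled); both carry a log-uniform prior
(D ∈ [0.0039, 16] μm²min⁻¹, χ ∈ [0.25, 16]).  All internal inference and
surrogate coordinates are (log₁₀D, log₁₀χ); χ is stored alongside the
scaled rates so the coordinates round-trip exactly.

Unit conventions: volumes convert as 1 μm³ = 10⁻¹⁵ L with
N_A = 6.022×10²³, so k [M⁻¹min⁻¹] ↔ k·10¹⁵/N_A [μm³min⁻¹]
(10⁹ M⁻¹min⁻¹ = 1.661 μm³min⁻¹).

### Diffusion-limited association

All three simulators use the Collins–Kimball effective rate
k_eff = k_a·k_D/(k_a + k_D) with the Smoluchowski encounter rate
k_D = 4πσD.  The reaction radius σ is not an independent measurement; it
is set to the radius whose encounter rate equals k_a at the base
D = 0.6 (σ ≈ 0.2202 μm), so the base system is exactly half
diffusion-limited and the (D, χ) sweep spans the diffusion-limited to the
reaction-limited regime.  σ is exposed for overrides.

## Simulators

**WMM.** Gillespie direct-method SSA over (G_free, G_bound, mRNA, P) with
the binding propensity k_eff/(N_A·V_cell) per gene–protein pair.  The SSA
kernel is a generic mass-action engine (numba-compiled) driven by the
declarative reaction network, so stoichiometry-level invariants (gene copy
conservation) are testable independently of the kernel.

**CBM.** The same engine over compartment-resolved species
(mRNA_nuc/cyt, P_nuc/cyt): transcription feeds the nuclear mRNA pool,
translation only consumes cytoplasmic mRNA, binding only nuclear protein
(propensity k_eff/(N_A·V_nuc)), and both mobile species hop both ways.
Hop rates come from hitting-time analysis of the Smoluchowski model with
uniform starting positions:

* k_exit = 1/τ̄_in with τ̄_in = r²/(15D) (uniform start inside the
  nucleus, absorbing boundary at r);
* k_entry = 1/τ̄_out with τ̄_out the shell-averaged closed form
  τ(ρ) = (1/D)[(R³/3)(1/r − 1/ρ) − (ρ² − r²)/6], weight 3ρ²/(R³ − r³),
  reflecting outer wall.

Both are linear in D.  A known consequence of MFPT-derived rates: they do
not satisfy uniform-occupancy detailed balance (equilibrium nuclear
occupancy k_entry/(k_entry+k_exit) ≈ 0.040 versus the volume fraction
0.072), so the CBM retains a small D-independent offset from the WMM even
at high D.  Measured whole-cell mean differences still shrink
monotonically with D (the acceptance check), but they do not vanish; this
is a property of the model definition, not of the implementation.

**SPATIAL.** Fixed-step Brownian dynamics (default Δt = 0.01 min,
validated against a halved step in the calibration tests): each molecule
takes independent Gaussian steps with per-axis variance 2DΔt; the cell
membrane reflects (specular, exact for a flat boundary by the image
method); the nuclear envelope is freely permeable; the gene is fixed at
the origin.  Per-step reaction probabilities are 1 − exp(−rate·Δt);
transcription places mRNA at the gene, translation requires |x| > r and
places the protein at its mRNA, a free gene absorbs the closest protein
whose end-of-step distance to the origin is below the binding radius σ_b,
and an unbinding event releases the protein at (1+10⁻³)·σ_b in a random
direction (avoiding deterministic instant rebinding; geminate
recombination realism is out of scope).

### Binding-radius calibration

End-of-step contact detection misses within-step crossings, so the radius
that realizes a target volumetric rate k_eff differs from the continuum
Smoluchowski radius k_eff/(4πD).  The calibration solves the discrete-time
pair problem deterministically: the steady-state pair density under the
exact radial propagator of one Gaussian step

    p(r | r′) = r/(r′ s√(2π)) · [e^{−(r−r′)²/2s²} − e^{−(r+r′)²/2s²}],  s² = 2DΔt,

is iterated on a radial mesh (dr = min(s/8, σ/10)) with an absorbing
region r < σ and a unit reservoir beyond L = σ + 12s; the continuum
resistance 1/(4πDL) of the region outside the mesh is added in series.
The resulting rate-vs-radius curve is monotone and noise-free, and σ_b is
its root (Brent).  Limits are verified in tests: 4πσD for s ≪ σ, the
swept volume (4/3)πσ³/Δt for s ≫ σ.  When s < 0.1·σ_smol the continuum
radius is returned directly (the residual bias is below the test
tolerances).  An independent Monte-Carlo oracle — mean absorption-cycle
time of walkers in a spherical shell, mapped through the closed-form
shell MFPT — cross-checks the calibrated radius at the base parameter
point to within 5%; the shell oracle is only valid when the shell spans
many steps, so it is not used in the large-step regime.

### Burn-in and initial condition

Simulations start from a free gene and zero molecules; samples are taken
at t_burn + i·Δt_sample.  The full-scale default t_burn = 500 min was
checked against the slowest relaxation scale (protein autocorrelation
decays well below 0.1 by 500 min at the slowest χ = 0.25, where
1/γ = 100 min); desk-scale fixtures use 200–400 min with windows chosen
long relative to 1/γ at χ = 1.

## Data scenarios

Ensembles (trajectories × times × species, integer counts) serialize to a
versioned JSON schema and HDF5 grid archives; per-trajectory seeds are
recorded so any ensemble regenerates bitwise from its manifest.  Scenario
operators: time coarsening keeps round(linspace(0, N−1, n)) indices —
endpoints always survive, so 100 → 3 keeps {0, 50, 99}; trajectory
subsampling draws without replacement, seeded; species restriction slices
the species axis.  The operators act on independent axes and commute.

## Features and distances

The per-species candidate pool holds 18 time-series features (sum,
absolute energy, mean absolute change, mean change, median, mean, length,
standard deviation, skewness, kurtosis, longest strike below/above the
mean, first/last location of maximum/minimum, maximum, minimum).
Conventions the definitions leave open: population (N-divisor) standard
deviation and moment ratios; kurtosis is the excess value; strike runs use
strict inequality; location features are occurrence indices normalised by
length (first = index/N, last = (index+1)/N); moment ratios of a constant
series are defined as 0.  The "optimized" six-statistic set (longest
strike below/above mean, mean absolute change, maximum, minimum, spread)
carries its spread slot under the pool's standard-deviation name — the
monotone equivalent of the variance.

Statistic-based distances average each feature over trajectories per
species and take the plain (unscaled) L2 norm of the difference; a
z-scored variant exists behind a flag, off by default.  The Kolmogorov
distance computes, per (time, species), the two-sample Kolmogorov
statistic sup|F_obs − F_sim| between the empirical count distributions
over trajectories (exact ECDFs on integer counts) and averages over all
pairs; the Kolmogorov-on-statistics variant applies the same statistic to
per-trajectory feature values.

## Summary-statistic selection (approximate sufficiency)

Candidates are tested in random order; one is kept when adding it changes
the approximate posterior materially.  "Materially" means the supremum
binwise |log posterior-density ratio| over both log-parameter marginals
(20 bins across the prior box, pseudo-count 1) exceeds both a fixed
threshold (log 4) and a bootstrap noise floor — the largest shift obtained
by resampling the current posterior three times — so finite-sample
histogram noise cannot masquerade as information.  Because the walk order
matters, the procedure repeats (default 20 shuffles) and reports
per-candidate selection frequencies; the top-k most frequent form the
chosen subset.  Cheap posteriors come from a reference-table backend:
rejection ABC against precomputed feature tables (per-feature standardised
L2, closest 20% accepted), which costs array slicing per subset.  Failed
repeats are skipped and surfaced, never silently absorbed.

## GP surrogate of the distance

For one observed ensemble, the training set pairs every grid point's
(log₁₀D, log₁₀χ) with the distance from the observed ensemble to the
ensemble simulated there.  Each simulated ensemble is split into two
halves to give two stochastic distance replicates per point — at full
scale this turns the 256-point grid into 512 training samples without new
simulation, and it gives the white-noise kernel genuine replicate
information.  The kernel is a rational quadratic plus white noise,

    k₁ = (1 + d²/(2αl²))^(−α),  k₂ = γ_noise·1[x = x′],  k = k₁ + k₂,

fitted by maximising the log marginal likelihood with L-BFGS-B and
restarts (scikit-learn backend, targets normalised internally; the
surrogate's own closed-form kernels back the unit tests via a dense
linear-algebra oracle).  Predictions return the noisy-observation mean and
standard deviation (the white term included), matching what a fresh
simulated distance would look like; ABC samples distances from
Normal(mean, sd) truncated below at zero (sd floored at 10⁻¹²).  A
held-out standardized-residual diagnostic is available and flags fits with
more than 5% of |z| > 3.

## ABC-SMC

Inference runs in log-parameter space where the prior is a uniform box.
Defaults (not printed in any reference; standard SMC practice at desk
scale): population 200, 8 generations, initial ε at the median of 1000
pilot prior-level distances, subsequent ε the median of the previous
generation's accepted distances (non-increasing by construction), Gaussian
perturbation kernel with twice the weighted population covariance,
out-of-prior proposals redrawn, standard kernel-mixture importance
weights, failure on effective sample size below 5 or on an exhausted trial
budget.  Distance backends are vectorised over proposal batches so the
surrogate mode amortises GP prediction; surrogate-mode inference performs
zero simulator calls (asserted via a call counter).  A direct-simulation
backend exists for small-scale validation.

## Error metrics and summaries

Expected log-error ε is the posterior-weighted mean Euclidean norm of the
log₁₀ parameter difference — zero only for a point mass at truth, growing
with both bias and width.  The RMSE variant is reported in linear
parameter units (a log-space flag exists for sensitivity checks).  Error
maps carry one value per grid point with failed inferences flagged, never
zeroed.  Boxen (letter-value) summaries report the quartiles and the
successive 2⁻ⁿ tail quantiles down to the one-observation resolution
floor, with linear interpolation between order statistics.

## Pipeline, seeds, caching

A run enumerates one task per (setup = metric × scenario, grid point,
inference model); the full-scale configuration gives 768 tasks per setup
(256 points × 3 models).  All per-task and per-trajectory seeds derive
from the single root seed through a splittable SeedSequence tree keyed by
task indices, so the plan and all outputs are independent of execution
order and bitwise reproducible; artifacts carry the config content hash,
and completed tasks are skipped on resume (posteriors are re-read from
disk even on first computation so fresh and resumed runs are
byte-identical).

### Problem sizes

The shipped configurations: *smoke* (3×3 grid, WMM truth, 4×10-sample
ensembles), *desk* (4×4 grid, CBM truth, WMM+CBM inference, 8×20-sample
ensembles, ~25 s per seed end-to-end), *full* (the original study
dimensions, 16×16 × 64×100 × three models — hundreds of core-hours,
emitted for cluster use).  Tests and the acceptance script run the smoke
and desk scales; the desk scale reproduces the *direction* of the fidelity
finding (matching-model inference beats the coarser model), not the
original error-map values.

## What the synthetic data do and do not show

The generator produces "perfect synthetic data": ensembles from the models
themselves, with no measurement noise, no cell-to-cell parameter
variability, and no misspecification beyond the fidelity gap between
simulators.  Passing tests therefore demonstrate the correctness of the
simulators, metrics, surrogate and sampler, and the internal consistency
of the pipeline's conclusions under its own models — not robustness to
experimental noise.  Observed data in every experiment sit on grid nodes
(the study design reuses the grid ensembles as observed data); off-node
truths in steep regions of the distance surface are not representable by a
coarse desk-scale surrogate, and the coverage tests respect that design.

## Known limitations

* The CBM's MFPT hop rates break uniform-occupancy detailed balance (see
  above); its high-D limit is offset from the WMM by construction.
* The WMM translates nuclear mRNA too (it has no compartments), so even
  the spatial model's high-D means differ from it by the nuclear mRNA
  fraction; convergence checks are therefore directional (monotone), not
  asymptotically exact.
* D is weakly identifiable in the reaction-limited (high-D) region — the
  distance surface flattens, and error maps show this honestly.
* The GP surrogate adds approximation error that is not separately
  quantified here beyond the held-out-residual diagnostic; the diagnostic
  is a proxy, not a calibrated utility measure.
* The binding-radius calibration assumes an isolated gene–protein pair;
  crowding and competing reactions within one step are neglected
  (consistent with the simulator's one-binding-per-step rule).
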