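"""Three fidelities of stochastic simulator for the negative-feedback gene.

* ``simulate_wmm`` — whole cell well mixed, exact SSA (Gillespie direct).
* ``simulate_cbm`` — nucleus and cytoplasm each well mixed, coupled by
  first-passage hop rates, exact SSA over compartment-resolved species.
* ``simulate_spatial`` — fixed-step Brownian dynamics of every molecule with
  a calibrated gene-binding radius (Smoluchowski-fidelity particle model).

All three emit whole-cell (mRNA, protein) copy-number time series and share
the same macroscopic rate constants, with the gene-protein association made
diffusion-limited through the Collins-Kimball combination, so that the
diffusion coefficient enters every fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _bd, _ssa, units
from .core import ParameterSet, compartment_network, whole_cell_network

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "CompartmentRates",
    "SimulationOverflowError",
    "effective_association_rate",
    "compartment_rates",
    "binding_radius",
    "simulate_wmm",
    "simulate_cbm",
    "simulate_spatial",
    "simulate",
    "without_feedback",
    "simulator_call_count",
    "reset_simulator_call_count",
]

#: Gene-protein reaction radius (um): the Smoluchowski radius that matches
#: the intrinsic ka at the base diffusion coefficient D = 0.6, so the base
#: system sits in the diffusion-influenced regime.  Exposed for overrides.
DEFAULT_REACTION_RADIUS = units.per_molar_to_um3(1.0e9) / (4.0 * math.pi * 0.6)

MODELS = ("WMM", "CBM", "SPATIAL")

_sim_calls = 0


def simulator_call_count() -> int:
    """Number of trajectory simulations since the last reset (any model)."""
    return _sim_calls


def reset_simulator_call_count() -> None:
    global _sim_calls
    _sim_calls = 0


def _count_call() -> None:
    global _sim_calls
    _sim_calls += 1


class SimulationOverflowError(RuntimeError):
    """Copy numbers exceeded the configured cap (runaway parameters)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling layout shared by all simulators.

    t_burn discards the transient from the zero-molecule initial condition;
    samples are recorded at t_burn + i * dt_sample for i = 0..n_samples-1.
    dt_bd is the Brownian-dynamics step, only used by the particle model.
    """

    t_burn: float = 500.0
    n_samples: int = 100
    dt_sample: float = 10.0
    dt_bd: float = 0.01
    seed: int = 0
    count_cap: int = 1_000_000
    particle_cap: int = 50_000

    def __post_init__(self) -> None:
        if self.t_burn <= 0 or self.dt_sample <= 0 or self.dt_bd <= 0:
            raise ValueError("all durations must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.dt_bd > self.dt_sample / 100.0:
            raise ValueError(
                f"dt_bd={self.dt_bd} too coarse for dt_sample={self.dt_sample} "
                "(require dt_bd <= dt_sample/100)"
            )

    def sample_times(self) -> np.ndarray:
        return self.t_burn + self.dt_sample * np.arange(self.n_samples)


@dataclass(frozen=True)
class Trajectory:
    """One replicate time series of whole-cell (mRNA, P) copy numbers."""

    times: np.ndarray
    counts: np.ndarray  # (n_samples, 2) int64, columns (mRNA, P)
    model: str
    D: float
    chi: float

    species = ("mRNA", "P")

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.times), 2):
            raise ValueError("counts must be (n_samples, 2)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def without_feedback(params: ParameterSet) -> ParameterSet:
    """Open-loop variant: gene-protein binding switched off (ka -> 0+).

    With the feedback absent the network is a linear birth-death cascade
    with stationary means mRNA = mu/gamma and P = kappa*mu/gamma^2.
    """
    return replace(params, ka=1e-30)


def effective_association_rate(ka: float, D: float, sigma: float) -> float:
    """Diffusion-limited association rate (M^-1 min^-1), Collins-Kimball.

    Combines the intrinsic rate ka with the Smoluchowski encounter rate
    kD = 4*pi*sigma*D harmonically: k_eff = ka*kD/(ka+kD), so the reaction
    is intrinsic-limited for fast diffusion and diffusion-limited for slow.
    """
    if ka <= 0 or D <= 0 or sigma <= 0:
        raise ValueError("ka, D and sigma must be positive")
    kD = units.um3_to_per_molar(4.0 * math.pi * sigma * D)
    return ka * kD / (ka + kD)


@dataclass(frozen=True)
class CompartmentRates:
    """Nucleus <-> cytoplasm hop rates (min^-1), both linear in D."""

    k_exit: float
    k_entry: float


def shell_mfpt(inner: float, outer: float, D: float) -> float:
    """Mean first-passage time (min) to the inner sphere for a Brownian
    particle started uniformly in the shell [inner, outer] with a
    reflecting outer wall:

        tau(rho) = (1/D) [ (b^3/3)(1/a - 1/rho) - (rho^2 - a^2)/6 ]

    averaged with weight 3 rho^2 / (b^3 - a^3), a = inner, b = outer.
    """
    if not (0 < inner < outer) or D <= 0:
        raise ValueError("need 0 < inner < outer and D > 0")
    a, b = inner, outer
    A = b**3 / (3.0 * D)
    shell = b**3 - a**3
    term1 = A * (shell / (3.0 * a) - (b**2 - a**2) / 2.0)
    term2 = ((b**5 - a**5) / 5.0 - a**2 * shell / 3.0) / (6.0 * D)
    return 3.0 / shell * (term1 - term2)


def compartment_rates(D: float, r: float, R: float) -> CompartmentRates:
    """First-passage hop rates between nucleus and cytoplasm.

    k_exit is the inverse of the mean first-passage time to the nuclear
    boundary from a uniform start inside the nucleus, tau_in = r^2/(15 D).
    k_entry inverts the uniform-start mean first-passage time to the inner
    sphere within the shell [r, R] with a reflecting outer wall,
    tau(rho) = (1/D) [ (R^3/3)(1/r - 1/rho) - (rho^2 - r^2)/6 ],
    averaged with the shell weight 3 rho^2 / (R^3 - r^3).
    """
    if not (0 < r < R):
        raise ValueError("need 0 < r < R")
    if D <= 0:
        raise ValueError("D must be positive")
    tau_in = r**2 / (15.0 * D)
    tau_out = shell_mfpt(r, R, D)
    return CompartmentRates(k_exit=1.0 / tau_in, k_entry=1.0 / tau_out)


# ---------------------------------------------------------------------------
# Binding-radius calibration for the particle model
# ---------------------------------------------------------------------------

_radius_cache: dict[tuple, float] = {}


def binding_radius(
    k_eff_um3: float,
    D_rel: float,
    dt_bd: float,
) -> float:
    """Radius sigma_b whose absorb-on-contact dynamics at step dt_bd
    reproduce the volumetric association rate k_eff_um3 (um^3/min).

    Discrete-time contact detection misses barrier crossings inside a step,
    so the realized rate at a given radius falls below the continuum
    Smoluchowski value 4*pi*sigma*D; the radius is therefore calibrated by
    root-finding on the deterministic discrete_association_rate curve.
    When the rms step is tiny relative to the Smoluchowski radius (slow
    diffusion) the discretisation bias is negligible and the continuum
    radius is returned directly.
    """
    if k_eff_um3 <= 0 or D_rel <= 0 or dt_bd <= 0:
        raise ValueError("all calibration inputs must be positive")
    key = (round(k_eff_um3, 12), round(D_rel, 12), round(dt_bd, 12))
    if key in _radius_cache:
        return _radius_cache[key]

    sigma_smol = k_eff_um3 / (4.0 * math.pi * D_rel)
    step_sd = math.sqrt(2.0 * D_rel * dt_bd)
    if step_sd < 0.1 * sigma_smol:
        _radius_cache[key] = sigma_smol
        return sigma_smol
    # radius that sweeps the target volume per step: the s >> sigma limit.
    # the calibrated radius must exceed both limiting radii, which brackets
    # the (deterministic, strictly increasing) rate-vs-radius curve
    sigma_kin = (3.0 * k_eff_um3 * dt_bd / (4.0 * math.pi)) ** (1.0 / 3.0)
    lo = 0.6 * max(sigma_smol, sigma_kin)
    hi = 1.5 * (sigma_smol + sigma_kin)
    f = lambda sig: discrete_association_rate(sig, D_rel, dt_bd) - k_eff_um3
    f_lo, f_hi = f(lo), f(hi)
    for _ in range(6):
        if f_lo <= 0 <= f_hi:
            break
        if f_lo > 0:
            lo *= 0.6
            f_lo = f(lo)
        else:
            hi *= 1.6
            f_hi = f(hi)
    else:
        raise ValueError(
            "binding-radius calibration found no radius reproducing "
            f"k_eff={k_eff_um3} um^3/min at dt_bd={dt_bd}; dt_bd too coarse"
        )
    from scipy.optimize import brentq

    sigma_b = float(brentq(f, lo, hi, xtol=1e-5, rtol=1e-4))
    _radius_cache[key] = sigma_b
    return sigma_b


def discrete_association_rate(sigma: float, D_rel: float, dt_bd: float) -> float:
    """Volumetric association rate (um^3/min) realized by end-of-step
    contact detection at radius sigma with time step dt_bd, computed
    deterministically.

    The steady-state pair density obeys a fixed point of the exact radial
    propagator of one Gaussian step,

        p(r | r') = r / (r' s sqrt(2 pi)) [e^{-(r-r')^2/2s^2} - e^{-(r+r')^2/2s^2}],

    with s^2 = 2 D dt.  The density is iterated on a radial mesh with an
    absorbing region r < sigma and a unit reservoir beyond L; the remaining
    continuum resistance 1/(4 pi D L) outside the mesh is added in series.
    Free of Monte-Carlo noise, valid from the diffusion-limited (s << sigma)
    to the kinetic (s >> sigma) regime.
    """
    if sigma <= 0 or D_rel <= 0 or dt_bd <= 0:
        raise ValueError("all inputs must be positive")
    s = math.sqrt(2.0 * D_rel * dt_bd)
    L = sigma + 12.0 * s
    B = L + 6.0 * s  # sources beyond L (held at unit concentration)
    dr = min(s / 8.0, sigma / 10.0)
    r = (np.arange(int(round(B / dr))) + 0.5) * dr
    n_dom = r <= L
    ri = r[n_dom]
    # concentration-update kernel: c_new(r_i) = sum_j K[i, j] c(r_j)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = (
            (r[None, :] / (ri[:, None] * s * math.sqrt(2.0 * math.pi)))
            * (
                np.exp(-((ri[:, None] - r[None, :]) ** 2) / (2 * s * s))
                - np.exp(-((ri[:, None] + r[None, :]) ** 2) / (2 * s * s))
            )
            * dr
        )
    c = np.where(r[n_dom] >= sigma, 1.0, 0.0)
    reservoir = np.ones((~n_dom).sum())
    vol_w = 4.0 * math.pi * ri**2 * dr
    absorbed_prev = -1.0
    inner = ri < sigma
    for _ in range(20000):
        c_full = np.concatenate([c, reservoir])
        c_new = K @ c_full
        absorbed = float((c_new[inner] * vol_w[inner]).sum())
        c_new[inner] = 0.0
        c = c_new
        if absorbed_prev >= 0 and abs(absorbed - absorbed_prev) <= 1e-5 * max(
            absorbed, 1e-300
        ):
            absorbed_prev = absorbed
            break
        absorbed_prev = absorbed
    k_L = absorbed_prev / dt_bd
    if k_L <= 0:
        return 0.0
    return 1.0 / (1.0 / k_L + 1.0 / (4.0 * math.pi * D_rel * L))


def realized_association_rate(
    sigma: float,
    D_rel: float,
    dt_bd: float,
    seed: int = 404,
    target_events: int = 1000,
    b_factor: float = 8.0,
) -> float:
    """Volumetric rate (um^3/min) actually realized by end-of-step contact
    detection at radius sigma with time step dt_bd.

    Measured with the spherical-shell renewal estimator: walkers between an
    absorbing sphere sigma and a reflecting wall b are re-injected uniformly
    on absorption, so the continuum per-particle absorption rate is exactly
    1/shell_mfpt(sigma, b).  The measured discrete-time rate is mapped back
    through that closed form to an equivalent continuum absorbing radius
    sigma_hat, and the realized rate is 4*pi*sigma_hat*D_rel — this removes
    the finite-domain effect and leaves only the discretisation bias.
    """
    step_sd = math.sqrt(2.0 * D_rel * dt_bd)
    # the continuum mapping needs the shell to span many steps
    b = max(3.0 * sigma, b_factor * step_sd)
    tau_meas = _bd.shell_mean_absorption_time(
        sigma, D_rel, dt_bd, b, target_events, seed
    )
    # invert the closed-form shell MFPT for the equivalent continuum radius
    lo_s, hi_s = 1e-9 * b, 0.999 * b
    for _ in range(80):
        mid = 0.5 * (lo_s + hi_s)
        if shell_mfpt(mid, b, D_rel) > tau_meas:
            lo_s = mid  # too small a radius -> too slow absorption
        else:
            hi_s = mid
    sigma_hat = 0.5 * (lo_s + hi_s)
    return 4.0 * math.pi * sigma_hat * D_rel


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def _run_ssa(network, x0, config: SimulationConfig) -> np.ndarray:
    counts, status = _ssa.ssa_mass_action(
        network.stoichiometry_matrix(),
        network.order_matrix(),
        network.rate_constants(),
        np.asarray(x0, dtype=np.int64),
        config.sample_times(),
        int(config.seed) % (2**32 - 1),
        config.count_cap,
    )
    if status == _ssa.STATUS_OVERFLOW:
        raise SimulationOverflowError(
            f"copy numbers exceeded cap {config.count_cap}; runaway parameters"
        )
    return counts


def simulate_wmm(params: ParameterSet, config: SimulationConfig) -> Trajectory:
    """Whole cell as one well-mixed volume, exact Gillespie direct SSA."""
    _count_call()
    k_eff = effective_association_rate(params.ka, params.D, DEFAULT_REACTION_RADIUS)
    v_cell = units.sphere_volume_um3(params.R)
    net = whole_cell_network(params, units.pair_propensity(k_eff, v_cell))
    counts = _run_ssa(net, [1, 0, 0, 0], config)
    return Trajectory(
        times=config.sample_times(),
        counts=counts[:, 2:4].copy(),
        model="WMM",
        D=params.D,
        chi=params.chi,
    )


def simulate_cbm(params: ParameterSet, config: SimulationConfig) -> Trajectory:
    """Two-compartment multiscale SSA; reported counts are whole-cell sums."""
    _count_call()
    k_eff = effective_association_rate(params.ka, params.D, DEFAULT_REACTION_RADIUS)
    v_nuc = units.sphere_volume_um3(params.r)
    hops = compartment_rates(params.D, params.r, params.R)
    net = compartment_network(
        params,
        units.pair_propensity(k_eff, v_nuc),
        hops.k_exit,
        hops.k_entry,
    )
    counts = _run_ssa(net, [1, 0, 0, 0, 0, 0], config)
    whole_cell = np.stack(
        [counts[:, 2] + counts[:, 3], counts[:, 4] + counts[:, 5]], axis=1
    )
    return Trajectory(
        times=config.sample_times(),
        counts=whole_cell,
        model="CBM",
        D=params.D,
        chi=params.chi,
    )


def simulate_spatial(params: ParameterSet, config: SimulationConfig) -> Trajectory:
    """Brownian-dynamics particle model with a calibrated binding radius.

    Molecules take Gaussian steps of per-axis variance 2*D*dt_bd, reflect at
    the cell membrane, and pass freely through the nuclear boundary; the
    gene is fixed at the origin.
    """
    _count_call()
    k_eff = effective_association_rate(params.ka, params.D, DEFAULT_REACTION_RADIUS)
    k_eff_um3 = units.per_molar_to_um3(k_eff)
    if k_eff_um3 > 1e-12:
        # relative diffusion of the gene-protein pair: the gene is immobile
        sigma_b = binding_radius(k_eff_um3, params.D, config.dt_bd)
    else:
        sigma_b = 0.0  # feedback effectively off; no binding events
    unbind_radius = (1.0 + 1e-3) * sigma_b if sigma_b > 0 else 0.0
    counts, status = _bd.bd_simulate(
        params.D,
        params.R,
        params.r,
        params.mu,
        params.kappa,
        params.gamma,
        params.kd,
        sigma_b,
        unbind_radius,
        config.dt_bd,
        config.sample_times(),
        int(config.seed) % (2**32 - 1),
        config.particle_cap,
    )
    if status == _bd.STATUS_OVERFLOW:
        raise SimulationOverflowError(
            f"particle count exceeded cap {config.particle_cap}; runaway parameters"
        )
    return Trajectory(
        times=config.sample_times(),
        counts=counts,
        model="SPATIAL",
        D=params.D,
        chi=params.chi,
    )


_SIMULATORS = {
    "WMM": simulate_wmm,
    "CBM": simulate_cbm,
    "SPATIAL": simulate_spatial,
}


def simulate(model: str, params: ParameterSet, config: SimulationConfig) -> Trajectory:
    """Dispatch on the model tag ('WMM', 'CBM' or 'SPATIAL')."""
    try:
        fn = _SIMULATORS[model.upper()]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}") from None
    return fn(params, config)
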