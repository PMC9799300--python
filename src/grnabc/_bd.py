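"""Brownian-dynamics kernels for the particle-level simulator (numba).

Molecules take independent Gaussian steps (per-axis variance 2*D*dt, i.e.
discretised Fickian diffusion), are reflected at the cell membrane |x| = R,
and react with per-step probabilities 1 - exp(-rate*dt).  The gene sits
fixed at the origin (centre of the nucleus) and binds a protein whose
end-of-step distance to the origin falls below the calibrated binding
radius.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERFLOW = 1


@njit(cache=True, inline="always")
def _reflect(x, y, z, R):
    nrm = np.sqrt(x * x + y * y + z * z)
    if nrm > R:
        scale = (2.0 * R - nrm) / nrm
        if scale < 0.0:  # pathological step larger than the cell; clamp
            scale = R / nrm
        x *= scale
        y *= scale
        z *= scale
    return x, y, z


@njit(cache=True)
def bd_simulate(
    D,
    R,
    r_nuc,
    mu,
    kappa,
    gamma,
    kd,
    sigma_bind,
    unbind_radius,
    dt,
    sample_times,
    seed,
    cap,
):
    """Particle-model realization; returns (counts[(n_samples, 2)], status).

    Columns of counts are (mRNA, free protein), whole-cell totals.
    sample_times are absolute (burn-in included by the caller).
    """
    np.random.seed(seed)
    n_samples = sample_times.shape[0]
    out = np.zeros((n_samples, 2), dtype=np.int64)

    mx = np.empty(cap)
    my = np.empty(cap)
    mz = np.empty(cap)
    px = np.empty(cap)
    py = np.empty(cap)
    pz = np.empty(cap)
    n_m = 0
    n_p = 0
    gene_bound = False

    step_sd = np.sqrt(2.0 * D * dt)
    p_deg = 1.0 - np.exp(-gamma * dt)
    p_txn = 1.0 - np.exp(-mu * dt)
    p_tln = 1.0 - np.exp(-kappa * dt)
    p_unb = 1.0 - np.exp(-kd * dt)
    sigma2 = sigma_bind * sigma_bind

    t = 0.0
    isample = 0
    while isample < n_samples:
        t += dt
        # diffusion with reflecting cell membrane
        for i in range(n_m):
            x = mx[i] + step_sd * np.random.standard_normal()
            y = my[i] + step_sd * np.random.standard_normal()
            z = mz[i] + step_sd * np.random.standard_normal()
            mx[i], my[i], mz[i] = _reflect(x, y, z, R)
        for i in range(n_p):
            x = px[i] + step_sd * np.random.standard_normal()
            y = py[i] + step_sd * np.random.standard_normal()
            z = pz[i] + step_sd * np.random.standard_normal()
            px[i], py[i], pz[i] = _reflect(x, y, z, R)
        # degradation (swap-with-last removal)
        i = n_m - 1
        while i >= 0:
            if np.random.random() < p_deg:
                n_m -= 1
                mx[i] = mx[n_m]
                my[i] = my[n_m]
                mz[i] = mz[n_m]
            i -= 1
        i = n_p - 1
        while i >= 0:
            if np.random.random() < p_deg:
                n_p -= 1
                px[i] = px[n_p]
                py[i] = py[n_p]
                pz[i] = pz[n_p]
            i -= 1
        # transcription at the gene (origin) while unrepressed
        if not gene_bound and np.random.random() < p_txn:
            if n_m >= cap:
                return out, STATUS_OVERFLOW
            mx[n_m] = 0.0
            my[n_m] = 0.0
            mz[n_m] = 0.0
            n_m += 1
        # translation from cytoplasmic mRNA (|x| > nucleus radius)
        n_m_now = n_m
        for i in range(n_m_now):
            d2 = mx[i] * mx[i] + my[i] * my[i] + mz[i] * mz[i]
            if d2 > r_nuc * r_nuc and np.random.random() < p_tln:
                if n_p >= cap:
                    return out, STATUS_OVERFLOW
                px[n_p] = mx[i]
                py[n_p] = my[i]
                pz[n_p] = mz[i]
                n_p += 1
        # gene binding: closest protein within the binding radius reacts
        if not gene_bound:
            best = -1
            best_d2 = sigma2
            for i in range(n_p):
                d2 = px[i] * px[i] + py[i] * py[i] + pz[i] * pz[i]
                if d2 <= best_d2:
                    best = i
                    best_d2 = d2
            if best >= 0:
                n_p -= 1
                px[best] = px[n_p]
                py[best] = py[n_p]
                pz[best] = pz[n_p]
                gene_bound = True
        elif np.random.random() < p_unb:
            # release at the unbinding radius, isotropic direction
            while True:
                ux = np.random.standard_normal()
                uy = np.random.standard_normal()
                uz = np.random.standard_normal()
                nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
                if nrm > 1e-12:
                    break
            if n_p >= cap:
                return out, STATUS_OVERFLOW
            px[n_p] = unbind_radius * ux / nrm
            py[n_p] = unbind_radius * uy / nrm
            pz[n_p] = unbind_radius * uz / nrm
            n_p += 1
            gene_bound = False

        while isample < n_samples and sample_times[isample] <= t + 1e-9:
            out[isample, 0] = n_m
            out[isample, 1] = n_p
            isample += 1
    return out, STATUS_OK


@njit(cache=True)
def diffuse_positions(D, R, dt, n_steps, n_mol, seed):
    """Reaction-free diffusion of n_mol molecules from the origin, with the
    same Gaussian-step/reflection rule as the full simulator; returns final
    positions (n_mol, 3).  Used to validate the kinematics in isolation."""
    np.random.seed(seed)
    step_sd = np.sqrt(2.0 * D * dt)
    pos = np.zeros((n_mol, 3))
    for _ in range(n_steps):
        for i in range(n_mol):
            x = pos[i, 0] + step_sd * np.random.standard_normal()
            y = pos[i, 1] + step_sd * np.random.standard_normal()
            z = pos[i, 2] + step_sd * np.random.standard_normal()
            pos[i, 0], pos[i, 1], pos[i, 2] = _reflect(x, y, z, R)
    return pos


@njit(cache=True, inline="always")
def _uniform_in_shell(sigma, b):
    """Uniform position in the shell sigma < |x| < b (rejection sampling)."""
    while True:
        x = np.random.uniform(-b, b)
        y = np.random.uniform(-b, b)
        z = np.random.uniform(-b, b)
        d2 = x * x + y * y + z * z
        if sigma * sigma < d2 < b * b:
            return x, y, z


@njit(cache=True)
def shell_mean_absorption_time(sigma, D_rel, dt, b, n_cycles, seed):
    """Mean time (min) for a discrete-time walker started uniformly in the
    shell sigma < |x| < b to make end-of-step contact with the inner
    sphere, with specular reflection at the outer wall.

    The continuum value of this mean is the closed-form uniform-start shell
    MFPT, so comparing the two isolates the pure time-discretisation bias
    of contact detection.  Averaging complete first-passage cycles (rather
    than counting absorptions in a fixed window) keeps the estimator free
    of renewal-transient bias.
    """
    np.random.seed(seed)
    step_sd = np.sqrt(2.0 * D_rel * dt)
    sigma2 = sigma * sigma
    max_steps = 20_000_000 // max(n_cycles, 1) + 100_000
    total = 0.0
    for _ in range(n_cycles):
        x, y, z = _uniform_in_shell(sigma, b)
        t = 0.0
        steps = 0
        while True:
            x += step_sd * np.random.standard_normal()
            y += step_sd * np.random.standard_normal()
            z += step_sd * np.random.standard_normal()
            x, y, z = _reflect(x, y, z, b)
            t += dt
            steps += 1
            if x * x + y * y + z * z < sigma2:
                break
            if steps >= max_steps:  # absorption far too slow at this radius
                break
        total += t
    return total / n_cycles
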