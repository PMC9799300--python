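"""Gillespie direct-method SSA kernel for mass-action networks (numba)."""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERFLOW = 1


@njit(cache=True)
def ssa_mass_action(stoich, orders, rates, x0, sample_times, seed, cap):
    """Exact SSA realization of a mass-action network.

    Parameters: stoich/orders are (n_reactions, n_species) int64 matrices,
    rates the deterministic rate constants (propensity = c * prod x^order,
    orders are 0/1 here — no homodimerisation in this network), x0 the
    initial counts, sample_times absolute recording times (sorted).

    Returns (counts[(n_samples, n_species)], status); status OVERFLOW when
    the total copy number exceeds cap (runaway parameters), in which case
    the counts array is only partially filled.
    """
    np.random.seed(seed)
    n_rx, n_sp = stoich.shape
    n_samples = sample_times.shape[0]
    x = x0.copy()
    out = np.zeros((n_samples, n_sp), dtype=np.int64)
    t = 0.0
    isample = 0
    a = np.empty(n_rx, dtype=np.float64)
    while isample < n_samples:
        # propensities
        a_tot = 0.0
        for j in range(n_rx):
            aj = rates[j]
            for k in range(n_sp):
                if orders[j, k] == 1:
                    aj *= x[k]
                elif orders[j, k] > 1:
                    for _ in range(orders[j, k]):
                        aj *= x[k]  # not used by this network; kept general
            a[j] = aj
            a_tot += aj
        if a_tot <= 0.0:
            # absorbing state: hold counts at all remaining sample times
            while isample < n_samples:
                for k in range(n_sp):
                    out[isample, k] = x[k]
                isample += 1
            break
        tau = -np.log(np.random.random()) / a_tot
        t_next = t + tau
        while isample < n_samples and sample_times[isample] < t_next:
            for k in range(n_sp):
                out[isample, k] = x[k]
            isample += 1
        if isample >= n_samples:
            break
        t = t_next
        u = np.random.random() * a_tot
        acc = 0.0
        jfire = n_rx - 1
        for j in range(n_rx):
            acc += a[j]
            if u < acc:
                jfire = j
                break
        total = 0
        for k in range(n_sp):
            x[k] += stoich[jfire, k]
            total += x[k]
        if total > cap:
            return out, STATUS_OVERFLOW
    return out, STATUS_OK
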