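"""Numba kernels for the expected-RT engine hot loops.

Pure-python/numpy equivalents of these loops live in `_engine`'s callers and
in :mod:`otem.accumulate`; the kernels only restate them element-wise for
speed.  Shapes: ``perceived`` is (n_trials, n_grid); ``rho`` is step-major
(n_steps + 1, n_trials).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def replay_kernel(perceived, update, alpha):
    """Pre-trial beliefs under delta-rule learning (exponential moving average)."""
    m, n = perceived.shape
    out = np.empty((m, n))
    p = np.full(n, 1.0 / n)
    for i in range(m):
        for j in range(n):
            out[i, j] = p[j]
        if update[i]:
            for j in range(n):
                p[j] = (1.0 - alpha) * p[j] + alpha * perceived[i, j]
    return out


@njit(cache=False)
def rho_kernel(pt, gamma, start_step, n_steps, exhausted):
    """Temporal gain on the within-trial step grid, step-major.

    ``pt`` is the belief matrix transposed to (n_grid, n_trials).  Suffix
    mass S and discounted suffix sum W are accumulated from the last grid
    point backwards; exhausted tails give rho = 1 (target imminent).
    """
    n, m = pt.shape
    out = np.empty((n_steps + 1, m))
    s = np.zeros(m)
    w = np.zeros(m)
    k = n_steps + 1 - start_step
    rho_grid = np.empty((n, m))
    for i in range(n - 1, -1, -1):
        for j in range(m):
            s[j] += pt[i, j]
            w[j] = pt[i, j] + gamma * w[j]
            if s[j] > exhausted:
                rho_grid[i, j] = w[j] / s[j]
            else:
                rho_grid[i, j] = 1.0
    for i in range(k):
        for j in range(m):
            out[start_step + i, j] = rho_grid[i, j]
    fac = 1.0
    for i in range(start_step - 1, -1, -1):
        fac *= gamma
        for j in range(m):
            out[i, j] = fac * w[j]
    return out


@njit(cache=False)
def euler_capture_kernel(rho, phi_c, phi_ic, mu, zeta, dt, onset_step, congruent):
    """Euler-integrate both preparedness threads; return the target thread's
    preparedness at each trial's target onset."""
    t1, m = rho.shape
    e_c = np.zeros(m)
    e_ic = np.zeros(m)
    at = np.zeros(m)
    for s in range(t1):
        for j in range(m):
            if onset_step[j] == s:
                at[j] = e_c[j] if congruent[j] else e_ic[j]
        if s < t1 - 1:
            for j in range(m):
                ec = e_c[j] + dt * (phi_c[s] * rho[s, j] - mu * e_c[j])
                eic = e_ic[j] + dt * (phi_ic[s] * rho[s, j] - mu * e_ic[j])
                e_c[j] = min(max(ec, 0.0), zeta)
                e_ic[j] = min(max(eic, 0.0), zeta)
    return at
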