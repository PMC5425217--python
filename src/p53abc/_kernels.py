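"""Numba-compiled integration kernels for the two-stage expression model.

All kernels operate on normalised rates (mRNA degradation rate = 1 is the
time unit) and simulate ``n`` independent cells from shared fixed initial
conditions, returning the final-time (mRNA, protein) state per cell.

Noise construction: the four reactions of the network never change both
species in the same event (translation is catalytic), so the per-species sum
of the per-reaction Wiener increments is itself Gaussian with variance equal
to the summed reaction propensities.  The kernels draw one increment per
species per step, which is distributionally identical to four independent
channels and halves the number of normal variates.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["euler_maruyama", "exponential_em", "gillespie"]


@njit(cache=True)
def euler_maruyama(k1, k2, k3, n, mrna_init, protein_init, dt, n_steps,
                   substeps, nonlinear, seed):
    """Fixed-step chemical-Langevin integration of n trajectories.

    ``substeps`` subdivides each nominal step for stiff parameter sets
    (protein decay rate >> 1); diffusion terms clamp states at zero under
    the square root and the state itself is clamped after each step.
    """
    np.random.seed(seed)
    m = np.full(n, mrna_init)
    p = np.full(n, protein_init)
    h = dt / substeps
    sqh = math.sqrt(h)
    for _ in range(n_steps * substeps):
        rm = np.random.standard_normal(n)
        rp = np.random.standard_normal(n)
        for i in range(n):
            mi = m[i]
            pi = p[i]
            deg = k3 * pi * pi if nonlinear else k3 * pi
            prod = k2 * mi
            mn = mi + (k1 - mi) * h + math.sqrt(k1 + mi) * sqh * rm[i]
            pn = pi + (prod - deg) * h + math.sqrt(prod + deg) * sqh * rp[i]
            m[i] = mn if mn > 0.0 else 0.0
            p[i] = pn if pn > 0.0 else 0.0
        if not (np.isfinite(m[0]) and np.isfinite(p[0])):
            break
    return m, p


@njit(cache=True)
def exponential_em(k1, k2, k3, n, mrna_init, protein_init, dt, n_steps, seed):
    """Linear-propagator (exponential) Euler-Maruyama step, linear model only.

    The linear drift is integrated exactly over each step and the diffusion,
    frozen at the step start, is filtered through the same exponential
    kernel.  Unconditionally stable in k3*dt and unbiased for the stationary
    mean and variance of both species, which makes it suitable for the
    stiff (k3 >> 1) regime the posterior occupies.
    """
    np.random.seed(seed)
    m = np.full(n, mrna_init)
    p = np.full(n, protein_init)
    em = math.exp(-dt)
    vm = (1.0 - math.exp(-2.0 * dt)) / 2.0
    ep = math.exp(-k3 * dt)
    vp = (1.0 - math.exp(-2.0 * k3 * dt)) / (2.0 * k3)
    r = k2 / k3
    for _ in range(n_steps):
        rm = np.random.standard_normal(n)
        rp = np.random.standard_normal(n)
        for i in range(n):
            mi = m[i]
            pi = p[i]
            mn = k1 + (mi - k1) * em + math.sqrt((k1 + mi) * vm) * rm[i]
            pn = r * mi + (pi - r * mi) * ep + \
                math.sqrt((k2 * mi + k3 * pi) * vp) * rp[i]
            m[i] = mn if mn > 0.0 else 0.0
            p[i] = pn if pn > 0.0 else 0.0
    return m, p


@njit(cache=True)
def gillespie(k1, k2, k3, n, mrna_init, protein_init, t_end, nonlinear,
              max_events, seed):
    """Exact SSA of the four-reaction network; returns (m, p, ok_flag)."""
    np.random.seed(seed)
    m_out = np.empty(n)
    p_out = np.empty(n)
    for i in range(n):
        m = float(mrna_init)
        p = float(protein_init)
        t = 0.0
        events = 0
        while True:
            a1 = k1
            a2 = m
            a3 = k2 * m
            a4 = k3 * p * p if nonlinear else k3 * p
            a0 = a1 + a2 + a3 + a4
            if a0 <= 0.0:
                break
            t += -math.log(np.random.random()) / a0
            if t > t_end:
                break
            events += 1
            if events > max_events:
                return m_out, p_out, False
            u = np.random.random() * a0
            if u < a1:
                m += 1.0
            elif u < a1 + a2:
                m -= 1.0
            elif u < a1 + a2 + a3:
                p += 1.0
            else:
                p -= 1.0
        m_out[i] = m
        p_out[i] = p
    return m_out, p_out, True
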