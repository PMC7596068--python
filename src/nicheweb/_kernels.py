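"""Compiled inner loops for the population dynamics.

The equilibrium relaxation is the hot path of the assembly loop (one call
per rewiring attempt), so it lives here as a numba kernel.  The scheme is
a positivity-preserving exponential Euler step on n_i' = n_i g_i — the
abundance is multiplied by exp(g_i dt), so trajectories started positive
stay positive and n_i = 0 is exactly absorbing — with a simple adaptive
step size, plus an optional Newton polish on the per-capita growth once
the integration has entered the equilibrium's neighbourhood.  The polish
never changes which equilibrium is reached: it is only attempted from a
small residual and is rejected if it leaves the positive orthant or
fails to shrink the residual below tolerance.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: abundances below this are clamped to exactly zero during relaxation
#: (far below any extinction threshold used by the experiments)
HARD_ZERO = 1e-14


@njit(cache=True)
def percapita_growth(nA, nP, rho_A, rho_P, beta_A, beta_P, gamma, theta, h):
    """Per-capita growth g for both guilds: dn_i/dt = n_i * g_i.

    g_i = rho_i - sum_j beta_ij n_j + (sum_k gamma_ik n_k) / (1 + h * sum_k theta_ik n_k)

    where the mutualism sums run over the opposite guild and the Holling
    denominator sums theta-weighted partner abundances only.
    """
    uA = theta @ nP          # partner abundance sums for guild A
    uP = theta.T @ nA
    gA = rho_A - beta_A @ nA + (gamma @ nP) / (1.0 + h * uA)
    gP = rho_P - beta_P @ nP + (gamma.T @ nA) / (1.0 + h * uP)
    return gA, gP


@njit(cache=True)
def _percap_jacobian(nA, nP, beta_A, beta_P, gamma, theta, h):
    """Jacobian of the per-capita growth (dg/dn), guild-blocked, M x M."""
    MA = nA.size
    MP = nP.size
    J = np.zeros((MA + MP, MA + MP))
    uA = theta @ nP
    uP = theta.T @ nA
    sA = gamma @ nP          # Holling numerators
    sP = gamma.T @ nA
    J[:MA, :MA] = -beta_A
    J[MA:, MA:] = -beta_P
    for i in range(MA):
        di = 1.0 + h * uA[i]
        for k in range(MP):
            J[i, MA + k] = gamma[i, k] / di - h * theta[i, k] * sA[i] / (di * di)
    for i in range(MP):
        di = 1.0 + h * uP[i]
        for k in range(MA):
            J[MA + i, k] = gamma[k, i] / di - h * theta[k, i] * sP[i] / (di * di)
    return J


@njit(cache=True)
def _residual(nA, nP, gA, gP):
    """max_i |dn_i/dt| = max_i |n_i g_i|."""
    r = 0.0
    for i in range(nA.size):
        v = abs(nA[i] * gA[i])
        if v > r:
            r = v
    for i in range(nP.size):
        v = abs(nP[i] * gP[i])
        if v > r:
            r = v
    return r


@njit(cache=True)
def relax(nA, nP, rho_A, rho_P, beta_A, beta_P, gamma, theta, h,
          tol, t_max, use_newton=True):
    """Relax abundances to equilibrium in place.

    Returns (residual, elapsed_time, converged).  Integration stops when
    max|dn_i/dt| < tol or the integrated time exceeds t_max.  When
    ``use_newton`` is set, a Newton solve of g(n) = 0 over the currently
    positive species is attempted once the residual is small (< 1e-4);
    a candidate is accepted only if it stays positive, moves the state
    by less than 0.1 in the max norm and lands below tolerance.
    """
    MA = nA.size
    MP = nP.size
    dt = 0.05
    dt_min = 1e-5
    dt_max = 1.5
    newton_from = 1e-2

    gA, gP = percapita_growth(nA, nP, rho_A, rho_P, beta_A, beta_P, gamma, theta, h)
    res = _residual(nA, nP, gA, gP)
    t = 0.0
    it = 0
    stall_res = res
    stall_it = 0
    while res > tol and t < t_max and it < 100000:
        it += 1
        # stall detection: a residual that refuses to shrink (frozen slow
        # mode) ends the relaxation early as non-converged
        if it - stall_it >= 300:
            if res > 0.98 * stall_res:
                break
            stall_res = res
            stall_it = it
        if use_newton and res < newton_from:
            ok = _newton_polish(nA, nP, rho_A, rho_P, beta_A, beta_P,
                                gamma, theta, h, tol)
            if ok:
                gA, gP = percapita_growth(nA, nP, rho_A, rho_P,
                                          beta_A, beta_P, gamma, theta, h)
                res = _residual(nA, nP, gA, gP)
                if res < tol:
                    return res, t, True
            use_newton = False  # one shot; fall back to integration

        # exponential Euler trial step
        trial_A = nA * np.exp(np.minimum(np.maximum(gA * dt, -30.0), 30.0))
        trial_P = nP * np.exp(np.minimum(np.maximum(gP * dt, -30.0), 30.0))
        tgA, tgP = percapita_growth(trial_A, trial_P, rho_A, rho_P,
                                    beta_A, beta_P, gamma, theta, h)
        tres = _residual(trial_A, trial_P, tgA, tgP)
        if tres > 1.2 * res and dt > dt_min:
            dt *= 0.5          # reject: step too aggressive
            continue
        # grow dt while descending, contract on a genuine rise; an exact
        # plateau keeps dt (the stall detector handles frozen modes)
        if tres < res:
            dt = min(dt * 1.2, dt_max)
        elif tres > res * 1.000001:
            dt = max(dt * 0.7, dt_min)
        nA[:] = trial_A
        nP[:] = trial_P
        for i in range(MA):
            if nA[i] < HARD_ZERO:
                nA[i] = 0.0
        for i in range(MP):
            if nP[i] < HARD_ZERO:
                nP[i] = 0.0
        gA, gP = tgA, tgP
        t += dt
        res = tres
        # retry Newton occasionally once the residual has shrunk again
        if not use_newton and it % 100 == 0 and res < newton_from:
            use_newton = True
    return res, t, res <= tol


@njit(cache=True)
def _newton_polish(nA, nP, rho_A, rho_P, beta_A, beta_P, gamma, theta, h, tol):
    """Newton iteration on g(n) = 0 restricted to positive species.

    Mutates nA/nP on success and returns True; leaves them untouched and
    returns False on any failure (singular step, sign change, large move,
    residual growth, or no convergence within 12 iterations).
    """
    MA = nA.size
    MP = nP.size
    M = MA + MP
    # active set: strictly positive species (zeros are absorbing)
    active = np.empty(M, dtype=np.bool_)
    for i in range(MA):
        active[i] = nA[i] > 1e-10
    for i in range(MP):
        active[MA + i] = nP[i] > 1e-10

    xA = nA.copy()
    xP = nP.copy()
    prev_res = 1e300
    for _ in range(12):
        gA, gP = percapita_growth(xA, xP, rho_A, rho_P, beta_A, beta_P,
                                  gamma, theta, h)
        res = _residual(xA, xP, gA, gP)
        if res < tol:
            # guard: polish must stay close to the integrated state so
            # it cannot hop to a different equilibrium's basin
            move = 0.0
            for i in range(MA):
                d = abs(xA[i] - nA[i])
                if d > move:
                    move = d
            for i in range(MP):
                d = abs(xP[i] - nP[i])
                if d > move:
                    move = d
            if move > 0.5:
                return False
            nA[:] = xA
            nP[:] = xP
            return True
        if res > prev_res:
            return False  # diverging: fail fast, resume integration
        prev_res = res
        J = _percap_jacobian(xA, xP, beta_A, beta_P, gamma, theta, h)
        g = np.empty(M)
        g[:MA] = gA
        g[MA:] = gP
        # freeze inactive (zero) species: identity row, zero rhs -> step 0
        for i in range(M):
            if not active[i]:
                for j in range(M):
                    J[i, j] = 0.0
                J[i, i] = 1.0
                g[i] = 0.0
        step = np.linalg.solve(J, g)
        bad = False
        for i in range(MA):
            if active[i]:
                xA[i] = xA[i] - step[i]
                if xA[i] <= 0.0:
                    bad = True
        for i in range(MP):
            if active[MA + i]:
                xP[i] = xP[i] - step[MA + i]
                if xP[i] <= 0.0:
                    bad = True
        if bad:
            return False
    return False
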