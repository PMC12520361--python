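"""Numba-compiled fixed-step RK4 integrator.

Model training evaluates the likelihood tens of thousands of times, which
rules out `scipy.integrate.solve_ivp` with a Python right-hand side.  The
functions here integrate the same vector field as :mod:`cycletime.model`
with classical RK4 at a fixed step (default 0.01 h); agreement with the
stiff reference solver is covered by the test suite.  Public entry points
accept :class:`~cycletime.model.ModelParameters` / `DrugCondition`; the
jitted kernels take flat arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import DrugCondition, ModelParameters

__all__ = ["integrate_fast", "integrate_batch", "pack_params"]

DEFAULT_DT = 0.01


@njit(cache=False)
def _rhs(s, q, gf, dnoco, dpalbo, E2Ft):
    # q: 15 kinetic params followed by 5 degradation rate constants
    p21, Cd, E2Fa, Ce, Ca, Cb = s[0], s[1], s[2], s[3], s[4], s[5]
    Vsp, Vsd, Vse, Vsa, Vsb = q[0], q[1], q[2], q[3], q[4]
    kx, kdd, kdd1, kde, kda, kdb = q[5], q[6], q[7], q[8], q[9], q[10]
    kpi, kpii, kpiii, IEn = q[11], q[12], q[13], q[14]
    Vdp, Vdd, Vde, Vda, Vdb = q[15], q[16], q[17], q[18], q[19]
    act = kpii / (kpii + p21)
    out = np.empty(6)
    out[0] = Vsp * E2Fa - Vdp * p21 * (Cb / (kx + Cb)) / (1.0 + IEn * dnoco)
    out[1] = Vsd * gf * E2Fa - Vdd * (Cd / (Cd + kdd))
    out[2] = (E2Ft - E2Fa) * (kpiii / (kpiii + Cb)) * (
        (Cd / (Cd + kdd1)) * dpalbo + Ce * (kpi / (kpi + p21))
    ) - E2Fa * Ca * act
    out[3] = Vse * E2Fa - Vde * (Ce / (Ce + kde)) * Ca * act
    out[4] = Vsa * E2Fa - Vda * (Ca / (Ca + kda))
    out[5] = Vsb * Ca * act - Vdb * (Cb / (Cb + kdb))
    return out


@njit(cache=False)
def _rk4_on_grid(s0, q, gf, dnoco, dpalbo, E2Ft, t_grid, dt):
    """Integrate and sample on an arbitrary increasing grid."""
    n_out = t_grid.shape[0]
    out = np.empty((n_out, 6))
    s = s0.astype(np.float64).copy()
    t = t_grid[0]
    out[0] = s
    for k in range(1, n_out):
        t_target = t_grid[k]
        while t < t_target - 1e-12:
            h = min(dt, t_target - t)
            k1 = _rhs(s, q, gf, dnoco, dpalbo, E2Ft)
            k2 = _rhs(s + 0.5 * h * k1, q, gf, dnoco, dpalbo, E2Ft)
            k3 = _rhs(s + 0.5 * h * k2, q, gf, dnoco, dpalbo, E2Ft)
            k4 = _rhs(s + h * k3, q, gf, dnoco, dpalbo, E2Ft)
            s = s + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        out[k] = s
    return out


@njit(cache=False)
def _rk4_batch_final(s0s, q, gf, dnoco, dpalbo, E2Ft, t_end, dt):
    """Final states after integrating each row of ``s0s`` for ``t_end``."""
    n = s0s.shape[0]
    out = np.empty((n, 6))
    nsteps = int(np.ceil(t_end / dt))
    h = t_end / nsteps
    for i in range(n):
        s = s0s[i].astype(np.float64).copy()
        for _ in range(nsteps):
            k1 = _rhs(s, q, gf, dnoco, dpalbo, E2Ft)
            k2 = _rhs(s + 0.5 * h * k1, q, gf, dnoco, dpalbo, E2Ft)
            k3 = _rhs(s + 0.5 * h * k2, q, gf, dnoco, dpalbo, E2Ft)
            k4 = _rhs(s + h * k3, q, gf, dnoco, dpalbo, E2Ft)
            s = s + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i] = s
    return out


def pack_params(params: ModelParameters) -> np.ndarray:
    """Flatten kinetic plus effective degradation constants for the kernels."""
    return np.concatenate([params.kinetic_array(), params.degradation_array()])


def integrate_fast(
    params: ModelParameters,
    init,
    condition: DrugCondition,
    t_grid,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """States on ``t_grid`` (shape ``(len(t_grid), 6)``) via fixed-step RK4."""
    t_grid = np.ascontiguousarray(t_grid, dtype=float)
    s0 = np.ascontiguousarray(
        init.to_array() if hasattr(init, "to_array") else init, dtype=float)
    return _rk4_on_grid(
        s0, pack_params(params), params.GF * condition.gf_scale,
        float(condition.delta_noco), float(condition.delta_palbo),
        params.E2Ft, t_grid, dt,
    )


def integrate_batch(
    params: ModelParameters,
    inits: np.ndarray,
    condition: DrugCondition,
    t_end: float,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Final states for a batch of initial conditions (``(n, 6)`` array)."""
    inits = np.ascontiguousarray(inits, dtype=float)
    if inits.ndim != 2 or inits.shape[1] != 6:
        raise ValueError("inits must be (n, 6)")
    return _rk4_batch_final(
        inits, pack_params(params), params.GF * condition.gf_scale,
        float(condition.delta_noco), float(condition.delta_palbo),
        params.E2Ft, float(t_end), dt,
    )
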