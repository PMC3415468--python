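"""Jitted fixed-step integration kernels.

The production integrator is a classical RK4 with pulse times aligned to step
boundaries, so a step never straddles a delta pulse: the jump is applied
between steps, exactly as a restart would.  Spike detection (upward crossings
of a fixed voltage level, linearly interpolated in time) happens inside the
kernel so long sweeps never materialize full trajectories.

The vector fields are the *same* Python functions as in
:mod:`relaybounds.model_core`, compiled here with numba; there is no second
transcription of the model equations in the integration path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model_core import _rhs2, _rhs3

_rhs2_jit = njit(cache=True)(_rhs2)
_rhs3_jit = njit(cache=True)(_rhs3)


@njit(cache=True)
def integrate2(P, x0, t0, dt, n_steps, pulse_steps, dv_jump,
               S0, S1, omega, level, cross_times, traj, store_stride,
               state_out):
    """RK4 over the 2nd-order model; returns the number of level crossings."""
    v = x0[0]
    h = x0[1]
    ptr = 0
    ncross = 0
    si = 0
    if store_stride > 0:
        traj[0, 0] = v
        traj[0, 1] = h
    for k in range(n_steps):
        t = t0 + k * dt
        jump_crossed = False
        if ptr < pulse_steps.size and pulse_steps[ptr] == k:
            # a jump across the level only counts as a spike if the dynamics
            # keep rising afterwards (regenerative); a jump landing on the
            # falling flank of a previous spike is not a new response
            jump_crossed = v < level and v + dv_jump >= level
            v = v + dv_jump
            ptr += 1
        sa = S0 + S1 * np.sin(omega * t)
        sb = S0 + S1 * np.sin(omega * (t + 0.5 * dt))
        sc = S0 + S1 * np.sin(omega * (t + dt))
        dv1, dh1 = _rhs2_jit(v, h, sa, P)
        dv2, dh2 = _rhs2_jit(v + 0.5 * dt * dv1, h + 0.5 * dt * dh1, sb, P)
        dv3, dh3 = _rhs2_jit(v + 0.5 * dt * dv2, h + 0.5 * dt * dh2, sb, P)
        dv4, dh4 = _rhs2_jit(v + dt * dv3, h + dt * dh3, sc, P)
        vn = v + dt / 6.0 * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
        hn = h + dt / 6.0 * (dh1 + 2.0 * dh2 + 2.0 * dh3 + dh4)
        if ncross < cross_times.size:
            if v < level and vn >= level:
                cross_times[ncross] = t + dt * (level - v) / (vn - v)
                ncross += 1
            elif jump_crossed and vn >= v:
                cross_times[ncross] = t
                ncross += 1
        v = vn
        h = hn
        if store_stride > 0 and (k + 1) % store_stride == 0:
            si += 1
            traj[si, 0] = v
            traj[si, 1] = h
    state_out[0] = v
    state_out[1] = h
    return ncross


@njit(cache=True)
def integrate3(P, x0, t0, dt, n_steps, pulse_steps, dv_jump,
               S0, S1, omega, level, cross_times, traj, store_stride,
               state_out):
    """RK4 over the 3rd-order model; returns the number of level crossings."""
    v = x0[0]
    h = x0[1]
    r = x0[2]
    ptr = 0
    ncross = 0
    si = 0
    if store_stride > 0:
        traj[0, 0] = v
        traj[0, 1] = h
        traj[0, 2] = r
    for k in range(n_steps):
        t = t0 + k * dt
        jump_crossed = False
        if ptr < pulse_steps.size and pulse_steps[ptr] == k:
            # a jump across the level only counts as a spike if the dynamics
            # keep rising afterwards (regenerative); a jump landing on the
            # falling flank of a previous spike is not a new response
            jump_crossed = v < level and v + dv_jump >= level
            v = v + dv_jump
            ptr += 1
        sa = S0 + S1 * np.sin(omega * t)
        sb = S0 + S1 * np.sin(omega * (t + 0.5 * dt))
        sc = S0 + S1 * np.sin(omega * (t + dt))
        dv1, dh1, dr1 = _rhs3_jit(v, h, r, sa, P)
        dv2, dh2, dr2 = _rhs3_jit(v + 0.5 * dt * dv1, h + 0.5 * dt * dh1,
                                  r + 0.5 * dt * dr1, sb, P)
        dv3, dh3, dr3 = _rhs3_jit(v + 0.5 * dt * dv2, h + 0.5 * dt * dh2,
                                  r + 0.5 * dt * dr2, sb, P)
        dv4, dh4, dr4 = _rhs3_jit(v + dt * dv3, h + dt * dh3,
                                  r + dt * dr3, sc, P)
        vn = v + dt / 6.0 * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
        hn = h + dt / 6.0 * (dh1 + 2.0 * dh2 + 2.0 * dh3 + dh4)
        rn = r + dt / 6.0 * (dr1 + 2.0 * dr2 + 2.0 * dr3 + dr4)
        if ncross < cross_times.size:
            if v < level and vn >= level:
                cross_times[ncross] = t + dt * (level - v) / (vn - v)
                ncross += 1
            elif jump_crossed and vn >= v:
                cross_times[ncross] = t
                ncross += 1
        v = vn
        h = hn
        r = rn
        if store_stride > 0 and (k + 1) % store_stride == 0:
            si += 1
            traj[si, 0] = v
            traj[si, 1] = h
            traj[si, 2] = r
    state_out[0] = v
    state_out[1] = h
    state_out[2] = r
    return ncross


def run(model_kind: int, pvec, x0, t0: float, dt: float, n_steps: int,
        pulse_steps, dv_jump: float, S0: float, S1: float, omega: float,
        level: float, store_stride: int = 0, max_cross: int | None = None):
    """Dispatch to the jitted kernel; returns (cross_times, traj, final_state).

    ``traj`` is None when ``store_stride == 0``, otherwise states sampled
    every ``store_stride`` steps (row 0 is the initial state).
    """
    P = tuple(float(p) for p in pvec)
    x0 = np.asarray(x0, dtype=float)
    pulse_steps = np.asarray(pulse_steps, dtype=np.int64)
    if max_cross is None:
        max_cross = int(n_steps * dt / 2.0) + 16
    cross = np.empty(max_cross, dtype=float)
    if store_stride > 0:
        traj = np.empty((n_steps // store_stride + 1, x0.size), dtype=float)
    else:
        traj = np.empty((1, x0.size), dtype=float)
    out = np.empty(x0.size, dtype=float)
    kern = integrate2 if model_kind == 2 else integrate3
    ncross = kern(P, x0, t0, dt, n_steps, pulse_steps, dv_jump,
                  S0, S1, omega, level, cross, traj, store_stride, out)
    return cross[:ncross].copy(), (traj if store_stride > 0 else None), out
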