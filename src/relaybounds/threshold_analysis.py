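"""Threshold structure of a relay neuron.

A stable relay neuron separates sub- from supra-threshold responses by a
critical hypersurface in state space.  This module quantifies the locally
relevant piece of that structure:

* ``I_th`` — the minimum delta-pulse height that elicits a successful
  response from the equilibrium (bisection), and the corresponding threshold
  voltage ``v_th = v_eq + I_th / C_m``;
* ``x_c`` — the post-jump state at threshold, a point on the hypersurface;
* the Jacobian eigendecomposition at ``x_c``, whose leading (positive) real
  eigenvalue's left eigenvector ``w_1`` measures the signed distance to the
  hypersurface;
* ``T_ref`` — the refractory period, from a two-pulse protocol;
* the *success-phase interval*: the set of modulating phases at which a pulse
  arriving on the steady-state orbit crosses the hypersurface,

  .. math:: \\Phi = \\{\\varphi : (\\alpha - I_{th})\\,w_{1,1}/C_m
            + S_1 |w_1^T H| \\sin(\\varphi + \\psi) > 0\\},

  with ``H = (j omega I - A)^{-1} B`` the orbit response and
  ``psi = arg(w_1^T H)``; ``P(X in S)`` is its length over ``2 pi``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .input_signals import ModulatingSignal, PulseTrain
from .linear_analysis import (LinearizationResult, find_equilibrium,
                              input_response_vector, jacobian_fd, linearize)
from .model_core import NeuronModel
from .simulator import (ResponseConfig, default_response_config, simulate,
                        _group_spikes)

__all__ = [
    "ThresholdInfo",
    "SuccessPhaseInterval",
    "CriticalLinearization",
    "threshold_current",
    "refractory_period",
    "critical_linearization",
    "DecisionKernel",
    "decision_kernel",
    "success_phase_interval",
    "prob_success",
    "phase_scan",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ThresholdInfo:
    """Threshold voltage/current and the critical point at a given ``S0``."""

    S0: float
    v_th: float                 # mV
    I_th: float                 # pulse-height units, µA·ms/cm²
    x_c: np.ndarray             # post-jump state at threshold
    alpha_tol: float            # bisection tolerance on I_th
    T_ref: float | None = None  # ms, filled by refractory_period
    vth_slope: float | None = None  # d v_th / d S0 diagnostic

    def to_json(self) -> str:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        return json.dumps(d)


@dataclass(frozen=True)
class SuccessPhaseInterval:
    """Wrapped phase interval (start, width) of successful pulse arrivals.

    ``width`` in ``[0, 2 pi]``; ``width == 2 pi`` means every phase succeeds,
    ``0`` means none.  ``constants`` echoes the scalars of the analytic
    criterion; ``fallback`` marks a numerically scanned (not analytic)
    interval.
    """

    start: float
    width: float
    constants: dict = field(default_factory=dict)
    fallback: bool = False

    @property
    def full(self) -> bool:
        return self.width >= TWO_PI - 1e-12

    @property
    def empty(self) -> bool:
        return self.width <= 1e-12

    def contains(self, phi) -> np.ndarray | bool:
        d = np.mod(np.asarray(phi, dtype=float) - self.start, TWO_PI)
        out = d < self.width
        return bool(out) if out.ndim == 0 else out

    def to_json(self) -> str:
        return json.dumps({"start": self.start, "width": self.width,
                           "constants": self.constants,
                           "fallback": self.fallback})


@dataclass(frozen=True)
class CriticalLinearization:
    """Eigendecomposition of the Jacobian at the critical point."""

    M: np.ndarray
    eigenvalues: np.ndarray     # sorted by descending real part
    W: np.ndarray               # right eigenvectors (columns)
    W_left: np.ndarray          # left eigenvectors (rows), bi-orthonormal
    lambda1_real: bool          # leading eigenvalue real (analytic path valid)


def _single_pulse_success(model, S0, alpha, config, dt, horizon) -> bool:
    """Does a lone pulse from the settled equilibrium elicit a response?

    Success is any detected response within the horizon, regardless of
    latency: near threshold the crossing is arbitrarily slow, so the relay
    scoring window does not apply here.
    """
    train = PulseTrain(np.array([0.0]), alpha, 0.0, 1.0)
    res = simulate(model, train, ModulatingSignal(S0, 0.0, 0.0), horizon,
                   config=config, warmup=0.0, record=False, dt=dt)
    return res.spike_times.size > 0


def threshold_current(model: NeuronModel, S0: float,
                      config: ResponseConfig | None = None,
                      alpha_max: float = 50.0, tol: float = 1e-3,
                      horizon: float = 400.0,
                      dt: float | None = None) -> ThresholdInfo:
    """Bisect the minimal pulse height that triggers a successful response.

    Run from the equilibrium at constant conductance ``S0`` (no modulation).
    Errors if even ``alpha_max`` fails.  The returned ``x_c`` is the
    post-jump state at threshold — the hypersurface point that near-threshold
    trajectories from the orbit actually visit.
    """
    config = config or default_response_config(model)
    x_eq = find_equilibrium(model, S0)

    def success(alpha):
        return _single_pulse_success(model, S0, alpha, config, dt, horizon)

    if not success(alpha_max):
        raise RuntimeError(
            f"no successful response up to alpha={alpha_max} at S0={S0}; "
            "not a relay regime")
    lo, hi = 0.0, float(alpha_max)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if success(mid):
            hi = mid
        else:
            lo = mid
    I_th = hi
    x_c = np.array(x_eq, dtype=float)
    x_c[0] += I_th / model.C_m
    return ThresholdInfo(S0=float(S0), v_th=float(x_c[0]), I_th=float(I_th),
                         x_c=x_c, alpha_tol=tol)


def vth_slope(model: NeuronModel, S0_grid, **kw):
    """Affine fit of ``v_th`` against ``S0``; returns (slope, intercept, R²)."""
    S0_grid = np.asarray(S0_grid, dtype=float)
    vth = np.array([threshold_current(model, s, **kw).v_th for s in S0_grid])
    coef = np.polyfit(S0_grid, vth, 1)
    pred = np.polyval(coef, S0_grid)
    ss_res = float(np.sum((vth - pred) ** 2))
    ss_tot = float(np.sum((vth - vth.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), float(coef[1]), r2, vth


def refractory_period(model: NeuronModel, S0: float, alpha: float,
                      config: ResponseConfig | None = None,
                      tol: float = 0.1, max_lag: float = 1000.0,
                      horizon: float = 400.0,
                      dt: float | None = None,
                      n_precondition: int = 0) -> float:
    """Smallest lag at which a pulse after a successful response succeeds.

    With ``n_precondition=0`` this is the classic two-pulse protocol: after a
    successful response to a first pulse of height ``alpha``, the lag of an
    identical second pulse is bisected; success of the second pulse is a new
    response (burst group) starting after it.  Requires ``alpha > I_th``
    (the first pulse must succeed).

    With ``n_precondition=k > 0`` the probe pair is preceded by ``k`` further
    pulses at the same lag, so the recovery is measured after a *typical*
    steady-state response rather than after an isolated one from rest.  Slow
    gates can accumulate over successive responses, making the sustained
    refractory longer than the isolated two-pulse one; the reliability
    bounds use the preconditioned variant for that reason.
    """
    config = config or default_response_config(model)
    sig = ModulatingSignal(S0, 0.0, 0.0)
    if not _single_pulse_success(model, S0, alpha, config, dt, horizon):
        raise RuntimeError(
            f"first pulse (alpha={alpha}) does not elicit a response at "
            f"S0={S0}; refractory_period needs alpha > I_th")

    def last_pulse_success(lag: float) -> bool:
        times = lag * np.arange(n_precondition + 2)
        train = PulseTrain(times, alpha, 0.0, 1.0)
        t_last = times[-1]
        res = simulate(model, train, sig, t_last + horizon, config=config,
                       warmup=0.0, record=False, dt=dt)
        groups = _group_spikes(np.sort(res.spike_times), config.burst_merge)
        return any(g[0] > t_last for g in groups)

    if not last_pulse_success(max_lag):
        raise RuntimeError(
            f"no recovery within max_lag={max_lag} ms; not a relay neuron "
            "at these settings")
    lo, hi = tol, float(max_lag)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if last_pulse_success(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def critical_linearization(model: NeuronModel, x_c: np.ndarray,
                           S0: float) -> CriticalLinearization:
    """Eigendecomposition of the Jacobian at the critical point.

    Eigenvalues are sorted by descending real part; for a point on the
    critical hypersurface the leading one has positive real part (trajectories
    divert from the surface).  Left eigenvectors are the rows of ``W^{-1}``,
    bi-orthonormal to the right ones by construction.
    """
    M = jacobian_fd(model, np.asarray(x_c, float), S0)
    lam, W = np.linalg.eig(M)
    order = np.argsort(-lam.real)
    lam, W = lam[order], W[:, order]
    condW = np.linalg.cond(W)
    if condW > 1e12:
        raise RuntimeError("defective (non-diagonalizable) Jacobian at x_c")
    W_left = np.linalg.inv(W)
    lambda1_real = bool(abs(lam[0].imag) < 1e-9 * max(1.0, abs(lam[0].real)))
    return CriticalLinearization(M=M, eigenvalues=lam, W=W, W_left=W_left,
                                 lambda1_real=lambda1_real)


@dataclass(frozen=True)
class DecisionKernel:
    """Adjoint sensitivity of the success decision along the critical trajectory.

    ``q0`` is the success functional at the pulse instant (normalized so its
    voltage component is 1 and points toward depolarization-success);
    ``K(tau) = q(tau) . B(x(tau))`` weights modulating input acting ``tau``
    ms after the pulse.  For a constant Jacobian this reduces to
    ``q0 = w1 / w11`` and ``K(tau) = (q0 . B_c) exp(-lambda1 tau)``.
    """

    tau: np.ndarray
    q0: np.ndarray
    K: np.ndarray

    def forcing_gain(self, omega: float) -> complex:
        """``int K(tau) exp(j omega tau) dtau`` — the continuing-input term."""
        return complex(np.trapezoid(self.K * np.exp(1j * omega * self.tau),
                                    self.tau))


def decision_kernel(model: NeuronModel, x_c: np.ndarray, S0: float,
                    T: float = 60.0, n_grid: int = 241) -> DecisionKernel:
    """Integrate the variational system along the critical trajectory.

    The fundamental matrix ``Psi`` of ``d(dx)/dt = J(x(t)) dx`` is computed
    from ``x_c``; its dominant left singular direction at ``T`` defines which
    initial deviations (and which forcing history) tip the trajectory across
    the hypersurface: ``q(tau) = u1^T Psi(T) Psi(tau)^{-1}``.
    """
    from scipy.integrate import solve_ivp

    x_c = np.asarray(x_c, dtype=float)
    n = x_c.size

    def rhs_aug(t, y):
        x = y[:n]
        Psi = y[n:].reshape(n, n)
        J = jacobian_fd(model, x, S0)
        return np.concatenate([model.rhs(x, S0), (J @ Psi).ravel()])

    ts = np.linspace(0.0, T, n_grid)
    sol = solve_ivp(rhs_aug, (0.0, T),
                    np.concatenate([x_c, np.eye(n).ravel()]),
                    t_eval=ts, rtol=1e-8, atol=1e-10, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"variational integration failed: {sol.message}")
    X = sol.y[:n].T
    Psis = sol.y[n:].T.reshape(-1, n, n)
    U, _, _ = np.linalg.svd(Psis[-1])
    q = np.einsum("i,ij,kjl->kl", U[:, 0], Psis[-1],
                  np.linalg.inv(Psis))
    if q[0, 0] < 0:
        q = -q
    q = q / q[0, 0]
    B_along = np.zeros_like(X)
    B_along[:, 0] = -(X[:, 0] - model.v_rev) / model.C_m
    K = np.einsum("ki,ki->k", q, B_along)
    return DecisionKernel(tau=ts, q0=q[0].copy(), K=K)


def success_phase_interval(model: NeuronModel, lin: LinearizationResult,
                           thr: ThresholdInfo, sig: ModulatingSignal,
                           alpha: float,
                           crit: CriticalLinearization | None = None,
                           kernel: DecisionKernel | None = None,
                           n_scan: int = 64) -> SuccessPhaseInterval:
    """Phases of the modulating cycle at which a pulse is relayed.

    Implements the linearized hypersurface-crossing criterion: a pulse of
    height ``alpha`` arriving at modulating phase ``phi`` succeeds iff

    ``(alpha - I_th) w11 / C_m + S1 |w1.H| sin(phi + psi) > 0``

    where ``w1`` is the leading left eigenvector at the critical point
    (sign-normalized so depolarization is the success direction).  Returns
    the full/empty interval in the always/never regimes.  If the leading
    eigenvalue is complex the analytic route is invalid and a brute-force
    phase scan is returned instead, flagged ``fallback``.
    """
    if sig.S1 == 0.0 or sig.omega == 0.0:
        width = TWO_PI if alpha > thr.I_th else 0.0
        return SuccessPhaseInterval(0.0, width,
                                    constants={"I_th": thr.I_th, "alpha": alpha})
    crit = crit or critical_linearization(model, thr.x_c, sig.S0)
    if not crit.lambda1_real:
        phis, succ = phase_scan(model, sig, alpha)
        return _interval_from_scan(phis, succ, fallback=True)
    if kernel is None:
        kernel = decision_kernel(model, thr.x_c, sig.S0)
    # Two routes for the modulation to tip the crossing: the orbit
    # displacement at the pulse instant (q0 . H) and the input continuing to
    # act while the trajectory diverts from the hypersurface, weighted by the
    # adjoint kernel K(tau):
    H = input_response_vector(lin, sig.omega)
    g = complex(kernel.q0 @ H) + kernel.forcing_gain(sig.omega)
    amp = sig.S1 * abs(g)
    psi = float(np.angle(g))
    a0 = (alpha - thr.I_th) / model.C_m          # q0 voltage component is 1
    gain_eff = abs(g) * model.C_m
    consts = {"I_th": thr.I_th, "alpha": alpha, "S1": sig.S1,
              "omega": sig.omega, "gain_eff": gain_eff, "psi": psi}
    if amp <= 0.0:
        return SuccessPhaseInterval(0.0, TWO_PI if a0 > 0 else 0.0, consts)
    c = -a0 / amp
    if c <= -1.0:
        return SuccessPhaseInterval(0.0, TWO_PI, consts)
    if c >= 1.0:
        return SuccessPhaseInterval(0.0, 0.0, consts)
    lo = float(np.arcsin(c))
    width = np.pi - 2.0 * lo
    start = float(np.mod(lo - psi, TWO_PI))
    return SuccessPhaseInterval(start, float(width), consts)


def prob_success(interval: SuccessPhaseInterval) -> float:
    """P(X in S): interval length over the full cycle (uniform pulse phase)."""
    return float(interval.width / TWO_PI)


def phase_scan(model: NeuronModel, sig: ModulatingSignal, alpha: float,
               n_phases: int = 64, config: ResponseConfig | None = None,
               horizon: float = 400.0, dt: float | None = None):
    """Brute-force oracle: classify a pulse at each of ``n_phases`` phases.

    Each run settles onto the orbit, injects one pulse at modulating phase
    ``phi`` and reports whether any response follows.  Returns
    ``(phases, success_bool_array)``.
    """
    from .linear_analysis import linearize, steady_state_orbit

    config = config or default_response_config(model)
    phis = np.arange(n_phases) * TWO_PI / n_phases
    succ = np.zeros(n_phases, dtype=bool)
    warmup = max(5.0 * sig.period, 500.0)
    orbit = steady_state_orbit(model, linearize(model, sig.S0), sig)
    x0 = orbit.state(-warmup)
    for i, phi in enumerate(phis):
        t_p = phi / sig.omega
        train = PulseTrain(np.array([t_p]), alpha, 0.0, 1.0)
        res = simulate(model, train, sig, t_p + horizon, config=config,
                       record=False, dt=dt, x0=x0, warmup=warmup)
        succ[i] = bool(np.any(res.spike_times > t_p))
    return phis, succ


def _interval_from_scan(phis: np.ndarray, succ: np.ndarray,
                        fallback: bool = True) -> SuccessPhaseInterval:
    """Wrapped interval covering the scanned success phases."""
    n = phis.size
    dphi = TWO_PI / n
    if not succ.any():
        return SuccessPhaseInterval(0.0, 0.0, fallback=fallback)
    if succ.all():
        return SuccessPhaseInterval(0.0, TWO_PI, fallback=fallback)
    # longest run of failures; the complement is the (wrapped) success interval
    ext = np.concatenate([~succ, ~succ])
    best_len, best_start, cur_len, cur_start = 0, 0, 0, 0
    for i, f in enumerate(ext):
        if f:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len and cur_len <= n:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    fail_start = best_start % n
    start = phis[(fail_start + best_len) % n]
    width = (n - best_len) * dphi
    return SuccessPhaseInterval(float(start), float(width), fallback=fallback)
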