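"""Linearization of the relay neuron about its undriven equilibrium.

With the modulating conductance held at its DC value ``S0`` a stable relay
neuron has a single globally attracting equilibrium ``x_eq``.  Writing
``s(t) = S0 + S1 sin(omega t)`` and linearizing about ``(x_eq, S0)`` gives an
LTI system ``dx' = A x' + B s'`` whose output (voltage) transfer function

.. math:: G(j\\omega) = C (j\\omega I - A)^{-1} B,
          \\quad B = -\\frac{v_{eq} - v_{rev}}{C_m}\\, e_1,\\quad C = e_1^T,

is a low-pass filter for these models.  The forced periodic solution — the
*steady-state orbit* — has per-component amplitude ``S1 |H_k|`` and phase
``arg H_k`` with ``H = (j omega I - A)^{-1} B``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .input_signals import ModulatingSignal
from .model_core import NeuronModel

__all__ = [
    "LinearizationResult",
    "OrbitTube",
    "find_equilibrium",
    "linearize",
    "jacobian_fd",
    "transfer_gain",
    "steady_state_orbit",
    "gain_surface",
]


def _reduced_voltage_residual(model: NeuronModel, v: float, S0: float) -> float:
    """Voltage derivative on the equilibrium manifold (gates at steady state)."""
    x = np.concatenate(([v], model.gate_steady_state(v)))
    return float(model.rhs(x, S0)[0])


def find_equilibrium(model: NeuronModel, S0: float,
                     v_range=(-110.0, -30.0), n_scan: int = 721) -> np.ndarray:
    """Locate the unique undriven equilibrium at constant conductance ``S0``.

    At any equilibrium the gate equations force the gates onto their
    steady-state curves, so the problem reduces to a scalar root-find in the
    voltage.  The reduced residual is scanned densely over the physiological
    range; exactly one sign change must be found (a stable relay neuron has a
    single equilibrium), otherwise an error reports all roots.
    """
    vv = np.linspace(*v_range, n_scan)
    gates = np.stack([np.atleast_1d(model.gate_steady_state(v)) for v in vv])
    X = np.column_stack([vv, gates])
    res = model.rhs(X, S0)[:, 0]
    sign = np.sign(res)
    idx = np.flatnonzero(np.diff(sign) != 0)
    roots = []
    for i in idx:
        r = brentq(lambda v: _reduced_voltage_residual(model, v, S0),
                   vv[i], vv[i + 1], xtol=1e-12)
        if not roots or abs(r - roots[-1]) > 1e-6:
            roots.append(r)
    if len(roots) == 0:
        raise RuntimeError(
            f"no equilibrium found for S0={S0} in v range {v_range}; "
            f"residual range [{res.min():.3g}, {res.max():.3g}]")
    if len(roots) > 1:
        raise RuntimeError(
            f"multiple equilibria at S0={S0} (v = {roots}); "
            "the stable-neuron assumption is violated")
    v_eq = roots[0]
    return np.concatenate(([v_eq], model.gate_steady_state(v_eq)))


def jacobian_fd(model: NeuronModel, x: np.ndarray, s: float,
                rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the vector field at ``(x, s)``.

    Step per component: ``rel_step * max(|x_i|, 1)`` — adequate for the smooth
    Boltzmann/exponential kinetics used here.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        hstep = rel_step * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += hstep
        xm[j] -= hstep
        J[:, j] = (model.rhs(xp, s) - model.rhs(xm, s)) / (2.0 * hstep)
    return J


@dataclass(frozen=True)
class LinearizationResult:
    """LTI approximation about the undriven equilibrium."""

    x_eq: np.ndarray
    S0: float
    A: np.ndarray           # n x n Jacobian at (x_eq, S0)
    B: np.ndarray           # input direction: -(v_eq - v_rev)/C_m into comp 0
    C: np.ndarray           # output selector of the voltage component
    eigenvalues: np.ndarray

    @property
    def v_eq(self) -> float:
        return float(self.x_eq[0])

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0))

    def gain(self, omega):
        return transfer_gain(self, omega)


def linearize(model: NeuronModel, S0: float,
              x_eq: np.ndarray | None = None) -> LinearizationResult:
    """Equilibrium linearization; errors if the equilibrium is not attracting."""
    if x_eq is None:
        x_eq = find_equilibrium(model, S0)
    A = jacobian_fd(model, x_eq, S0)
    n = x_eq.size
    B = np.zeros(n)
    B[0] = -(x_eq[0] - model.v_rev) / model.C_m
    C = np.zeros(n)
    C[0] = 1.0
    eig = np.linalg.eigvals(A)
    return LinearizationResult(x_eq=np.asarray(x_eq, float), S0=float(S0),
                               A=A, B=B, C=C, eigenvalues=eig)


def transfer_gain(lin: LinearizationResult, omega):
    """Exact evaluation of ``G(j omega) = C (j omega I - A)^{-1} B``.

    Vectorizes over ``omega``; returns complex values.
    """
    om = np.atleast_1d(np.asarray(omega, dtype=float))
    n = lin.A.shape[0]
    out = np.empty(om.size, dtype=complex)
    for i, w in enumerate(om):
        M = 1j * w * np.eye(n) - lin.A
        out[i] = lin.C @ np.linalg.solve(M, lin.B)
    return out[0] if np.isscalar(omega) or np.ndim(omega) == 0 else out


def input_response_vector(lin: LinearizationResult, omega: float) -> np.ndarray:
    """Full state response ``H = (j omega I - A)^{-1} B`` (complex n-vector)."""
    n = lin.A.shape[0]
    M = 1j * float(omega) * np.eye(n) - lin.A
    return np.linalg.solve(M, lin.B)


@dataclass(frozen=True)
class OrbitTube:
    """The forced periodic orbit plus an epsilon membership neighbourhood."""

    x_eq: np.ndarray
    amplitudes: np.ndarray      # per-component amplitude S1 |H_k|
    phases: np.ndarray          # per-component phase arg H_k (rad)
    omega: float
    epsilon: float

    @property
    def period(self) -> float:
        return np.inf if self.omega == 0 else 2.0 * np.pi / self.omega

    def state(self, t):
        """Point(s) on the orbit at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        osc = self.amplitudes * np.sin(self.omega * t[..., None] + self.phases)
        return self.x_eq + osc

    def contains(self, x, t=None) -> np.ndarray | bool:
        """Distance-to-orbit membership test (within ``epsilon``)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        tt = np.linspace(0.0, self.period if np.isfinite(self.period) else 1.0, 256)
        pts = self.state(tt)
        d = np.min(np.linalg.norm(x[:, None, :] - pts[None, :, :], axis=-1), axis=1)
        out = d <= self.epsilon
        return bool(out[0]) if out.size == 1 and np.ndim(x) <= 2 else out


def steady_state_orbit(model: NeuronModel, lin: LinearizationResult,
                       sig: ModulatingSignal,
                       small_signal_warn: float = 0.5) -> OrbitTube:
    """Analytic steady-state orbit for the sinusoidal modulating input.

    Valid in the small-signal regime; emits a warning when the predicted
    voltage swing exceeds ``small_signal_warn`` times the distance from the
    equilibrium to the edge of the scanned voltage band (a coarse proxy for
    the distance to threshold, which needs the threshold module to know).
    The tube radius defaults to 10% of the voltage amplitude with a 0.1 mV
    floor and is used only for diagnostics, never in the bound formulas.
    """
    if sig.omega == 0 or sig.S1 == 0:
        amps = np.zeros_like(lin.x_eq)
        phases = np.zeros_like(lin.x_eq)
        return OrbitTube(lin.x_eq, amps, phases, sig.omega, 0.1)
    H = input_response_vector(lin, sig.omega)
    amps = sig.S1 * np.abs(H)
    phases = np.angle(H)
    if amps[0] > small_signal_warn * 10.0:
        import warnings
        warnings.warn(
            f"voltage orbit amplitude {amps[0]:.2f} mV is large; the "
            "linearized orbit may be inaccurate", stacklevel=2)
    eps = max(0.1, 0.1 * amps[0])
    return OrbitTube(lin.x_eq, amps, phases, sig.omega, eps)


def gain_surface(model: NeuronModel, omega_grid, g_T_grid=None, g_L_grid=None,
                 S0: float = 0.0) -> pd.DataFrame:
    """``|G|`` over an (omega, g_T, g_L) grid, re-linearizing per point.

    Per-point failures are recorded in the ``error`` column rather than
    aborting the sweep.  Returns a tidy frame with columns
    ``g_T, g_L, omega, gain_abs, gain_phase, v_eq, error``.
    """
    from .model_core import load_model

    g_T_grid = [model.params["g_T"]] if g_T_grid is None else list(g_T_grid)
    g_L_grid = [model.params["g_L"]] if g_L_grid is None else list(g_L_grid)
    rows = []
    for g_T in g_T_grid:
        for g_L in g_L_grid:
            m = load_model(model.name, {"g_T": g_T, "g_L": g_L})
            try:
                lin = linearize(m, S0)
                G = transfer_gain(lin, np.asarray(omega_grid, float))
                for w, g in zip(np.atleast_1d(omega_grid), np.atleast_1d(G)):
                    rows.append(dict(g_T=g_T, g_L=g_L, omega=float(w),
                                     gain_abs=abs(g), gain_phase=float(np.angle(g)),
                                     v_eq=lin.v_eq, error=""))
            except Exception as exc:  # per-point failure is data, not fatal
                for w in np.atleast_1d(omega_grid):
                    rows.append(dict(g_T=g_T, g_L=g_L, omega=float(w),
                                     gain_abs=np.nan, gain_phase=np.nan,
                                     v_eq=np.nan, error=str(exc)))
    return pd.DataFrame(rows)
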