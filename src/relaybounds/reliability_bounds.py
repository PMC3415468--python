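"""Closed-form lower/upper bounds on relay reliability.

A driving pulse is relayed iff the state is back in the orbit tube when the
pulse arrives (event ``X in T``) *and* the modulating phase lies in the
success interval (event ``X in S``, probability ``P_S``).  After a successful
response the state needs ``T_ref`` ms to return to the tube; after an
unsuccessful one some unknown ``T_ref_u in [0, T_ref]``.  Bracketing
``T_ref_u`` by its extremes and using the survival probability of the
refractory-exponential interval law,

.. math:: p = P(T_i > T_{ref}) = e^{-\\lambda (T_{ref} - T_R)^+},

gives the stationary bounds

.. math:: P(X\\in T)_{lb} = p, \\qquad
          P(X\\in T)_{ub} = \\frac{1}{1 + P_S (1 - p)},

and ``R_lb = P_S p``, ``R_ub = P_S / (1 + P_S (1 - p))``.  Limiting cases:
sparse pulses (``p -> 1``) collapse both bounds to ``P_S``; with ``P_S = 1``
and dense pulses (``p -> 0``) the upper bound tends to 1/2 — each success is
followed by exactly one refractory-censored pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .input_signals import ModulatingSignal, interval_survival
from .linear_analysis import linearize
from .model_core import NeuronModel, load_model
from .simulator import ResponseConfig, default_response_config, empirical_reliability
from .threshold_analysis import (critical_linearization, decision_kernel,
                                 prob_success, refractory_period,
                                 success_phase_interval, threshold_current)

__all__ = [
    "ReliabilityBounds",
    "OperatingPoint",
    "prob_in_tube_bounds",
    "reliability_bounds",
    "bounds_at_point",
    "sweep_bounds",
    "spontaneous_extension",
]


@dataclass(frozen=True)
class OperatingPoint:
    """One full input condition of the relay neuron."""

    S0: float           # modulating DC offset, mS/cm²
    S1: float           # modulating amplitude, mS/cm²
    omega: float        # modulating angular frequency, rad/ms
    alpha: float        # driving pulse height, µA·ms/cm²
    lam: float          # driving exponential rate, 1/ms
    T_R_drive: float    # driving refractory floor, ms

    @property
    def signal(self) -> ModulatingSignal:
        return ModulatingSignal(self.S0, self.S1, self.omega)


@dataclass(frozen=True)
class ReliabilityBounds:
    """Reliability bracket and its ingredients at one operating point."""

    P_S: float
    T_ref: float
    p_survival: float           # P(T_i > T_ref)
    P_T_lb: float
    P_T_ub: float
    R_lb_raw: float
    R_ub_raw: float
    inputs: dict = field(default_factory=dict)

    @property
    def R_lb(self) -> float:
        """Lower bound clamped to [0, 1] (raw value kept for diagnostics)."""
        return float(min(max(self.R_lb_raw, 0.0), 1.0))

    @property
    def R_ub(self) -> float:
        return float(min(max(self.R_ub_raw, 0.0), 1.0))


def prob_in_tube_bounds(lam: float, T_R_drive: float, T_ref: float,
                        P_S: float) -> tuple[float, float]:
    """Bracket on P(state in orbit tube at a pulse arrival).

    Lower bound: every pulse — successful or not — is followed by the full
    refractory ``T_ref`` (``T_ref_u = T_ref``), so a pulse finds the tube iff
    its interval exceeds ``T_ref``.  Upper bound: only successes incur
    ``T_ref`` (``T_ref_u = 0``); stationarity of the per-pulse recursion
    gives ``1 / (1 + P_S (1 - p))``.
    """
    if min(lam, P_S) < 0 or T_R_drive < 0 or T_ref < 0 or P_S > 1:
        raise ValueError("arguments must be non-negative with P_S in [0, 1]")
    p = float(interval_survival(lam, T_R_drive, T_ref))
    lb = p
    ub = 1.0 / (1.0 + P_S * (1.0 - p))
    return lb, ub


def reliability_bounds(P_S: float, T_ref: float, lam: float,
                       T_R_drive: float, **inputs) -> ReliabilityBounds:
    """Compose ``P_S`` with the orbit-tube bracket into reliability bounds.

    Uses the stationary-phase assumption ``P(X in S | X in T) = P_S`` (the
    pulse phase relative to the modulating cycle is uniform).
    """
    lb_T, ub_T = prob_in_tube_bounds(lam, T_R_drive, T_ref, P_S)
    p = float(interval_survival(lam, T_R_drive, T_ref))
    return ReliabilityBounds(
        P_S=float(P_S), T_ref=float(T_ref), p_survival=p,
        P_T_lb=lb_T, P_T_ub=ub_T,
        R_lb_raw=float(P_S) * lb_T, R_ub_raw=float(P_S) * ub_T,
        inputs={"lam": lam, "T_R_drive": T_R_drive, **inputs})


def bounds_at_point(model: NeuronModel, point: OperatingPoint,
                    config: ResponseConfig | None = None,
                    _cache: dict | None = None) -> ReliabilityBounds:
    """Full pipeline at one operating point: equilibrium -> linearization ->
    threshold -> refractory -> success-phase interval -> bounds.

    ``_cache`` lets sweeps reuse stage results keyed on what the stage
    actually depends on.
    """
    config = config or default_response_config(model)
    cache = _cache if _cache is not None else {}
    mkey = id(model)

    k_lin = ("lin", mkey, point.S0)
    if k_lin not in cache:
        cache[k_lin] = linearize(model, point.S0)
    lin = cache[k_lin]

    k_thr = ("thr", mkey, point.S0)
    if k_thr not in cache:
        cache[k_thr] = threshold_current(model, point.S0, config=config)
    thr = cache[k_thr]

    k_crit = ("crit", mkey, point.S0)
    if k_crit not in cache:
        cache[k_crit] = critical_linearization(model, thr.x_c, point.S0)
    crit = cache[k_crit]

    k_kern = ("kern", mkey, point.S0)
    if k_kern not in cache and crit.lambda1_real:
        cache[k_kern] = decision_kernel(model, thr.x_c, point.S0)
    kern = cache.get(k_kern)

    # The two-pulse protocol needs a suprathreshold pulse.  For alpha at or
    # below I_th (successes then only happen at favourable phases) probe with
    # a just-suprathreshold height: T_ref is largest near threshold, which
    # widens — never invalidates — the bracket.
    alpha_probe = (point.alpha if point.alpha >= 1.01 * thr.I_th
                   else 1.01 * thr.I_th)
    k_ref = ("tref", mkey, point.S0, alpha_probe)
    if k_ref not in cache:
        # preconditioned protocol: slow-gate adaptation can make the
        # steady-state refractory longer than the isolated two-pulse one
        cache[k_ref] = refractory_period(model, point.S0, alpha_probe,
                                         config=config, n_precondition=4)
    T_ref = cache[k_ref]

    interval = success_phase_interval(model, lin, thr, point.signal,
                                      point.alpha, crit=crit, kernel=kern)
    P_S = prob_success(interval)
    return reliability_bounds(P_S, T_ref, point.lam, point.T_R_drive,
                              S0=point.S0, S1=point.S1, omega=point.omega,
                              alpha=point.alpha, I_th=thr.I_th,
                              fallback=interval.fallback)


_SWEEPABLE = ("omega", "S0", "lam", "alpha", "g_T", "g_L")


def sweep_bounds(model: NeuronModel, point: OperatingPoint, var: str, grid,
                 n_trials: int = 20, n_pulses: int = 200, seed=0,
                 config: ResponseConfig | None = None,
                 dt: float | None = None) -> pd.DataFrame:
    """Bounds and empirical reliability along a one-parameter sweep.

    ``var`` is one of ``omega, S0, lam, alpha, g_T, g_L``; all other inputs
    stay at ``point``.  Stage results are cached across grid points when the
    swept variable cannot affect them.  Per-point failures are recorded in
    the ``error`` column and the sweep continues.
    """
    if var not in _SWEEPABLE:
        raise ValueError(f"var must be one of {_SWEEPABLE}")
    config = config or default_response_config(model)
    cache: dict = {}
    ss = np.random.SeedSequence(seed)
    rows = []
    for value, child in zip(np.asarray(grid, dtype=float), ss.spawn(len(grid))):
        row = dict(var=var, value=float(value))
        try:
            if var in ("g_T", "g_L"):
                m = load_model(model.name, {var: float(value)})
                pt = point
            else:
                m = model
                pt = replace(point, **{var: float(value)})
            b = bounds_at_point(m, pt, config=config, _cache=cache)
            mean, sd, _ = empirical_reliability(
                m, pt.signal, pt.alpha, pt.lam, pt.T_R_drive,
                n_trials=n_trials, seed=child, n_pulses=n_pulses,
                config=config, dt=dt)
            row.update(P_S=b.P_S, T_ref=b.T_ref, R_lb=b.R_lb, R_ub=b.R_ub,
                       R_lb_raw=b.R_lb_raw, R_ub_raw=b.R_ub_raw,
                       R_emp_mean=mean, R_emp_sd=sd,
                       contained=bool(mean - sd <= b.R_ub + 1e-12
                                      and mean + sd >= b.R_lb - 1e-12),
                       error="")
        except Exception as exc:
            row.update(P_S=np.nan, T_ref=np.nan, R_lb=np.nan, R_ub=np.nan,
                       R_lb_raw=np.nan, R_ub_raw=np.nan,
                       R_emp_mean=np.nan, R_emp_sd=np.nan, contained=False,
                       error=str(exc))
        rows.append(row)
    df = pd.DataFrame(rows)
    for k in ("S0", "S1", "omega", "alpha", "lam", "T_R_drive"):
        df[f"base_{k}"] = getattr(point, k)
    return df


def spontaneous_extension(bounds: ReliabilityBounds,
                          T_noise: float) -> tuple[float, float]:
    """APPROXIMATE reliability adjustment for a spontaneously firing neuron.

    Spontaneous (limit-cycle) firing is modelled as a periodic noise pulse
    train of period ``T_noise`` whose responses are undesirable: reliability
    is re-scored as desirable minus undesirable successes per driving pulse,
    which subtracts about one noise response per ``T_noise`` interval, i.e.
    ``R' = R - (T_R + 1/lam) / T_noise``.  Reduces to the unadjusted bounds
    as ``T_noise -> inf``; can go negative for frequent noise (reported raw,
    never clamped — the approximation flag is this function's contract).
    """
    if T_noise <= 0:
        raise ValueError("T_noise must be positive")
    lam = bounds.inputs["lam"]
    T_R = bounds.inputs["T_R_drive"]
    penalty = (T_R + 1.0 / lam) / T_noise
    return bounds.R_lb - penalty, bounds.R_ub - penalty
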