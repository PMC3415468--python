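"""Conductance-based relay-neuron models.

A relay neuron is modelled as an :math:`n`-th order vector field

.. math::

    C_m \\dot v = -\\sum_i I_i(v, x) + I_{ext} - s(t)\\,(v - v_{rev}) + u(t),
    \\qquad
    \\dot x_j = \\phi_j\\,\\frac{x_{j\\infty}(v) - x_j}{\\tau_{x_j}(v)},

where the first state component is the membrane voltage (mV), the remaining
components are ion-channel gate probabilities in ``[0, 1]``, ``s(t)`` is an
inhibitory (modulating) synaptic conductance and ``u(t)`` a train of excitatory
(driving) current pulses.  Two concrete models are shipped:

``second_order``
    A minimal thalamic relay cell carrying only a low-threshold T-type calcium
    current (instantaneous activation, slow inactivation gate ``h``) and a leak
    current.  Kinetics follow the classic post-inhibitory-rebound thalamic cell
    of Wang & Rinzel, also used for inferior-olive subthreshold oscillations.

``third_order``
    The Rubin–Terman thalamocortical cell with leak, fast sodium, delayed
    rectifier potassium (its gate slaved to the sodium inactivation gate) and a
    T-type calcium current whose slow inactivation gate ``r`` is the third
    state.  Depending on the applied current it responds to a pulse with a
    single spike (tonic, depolarized) or a burst of spikes (hyperpolarized).

All numeric parameter values live in plain-text fixture files under
``relaybounds/fixtures`` (units and provenance in the comments); the code only
implements the functional forms.

Units, package-wide: mV, ms, µA/cm², mS/cm², µF/cm².  A driving pulse of
height ``alpha`` (µA·ms/cm²) instantly changes the voltage by ``alpha / C_m``.
"""

from __future__ import annotations

import importlib.resources
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ModelParameters",
    "NeuronModel",
    "MODEL_NAMES",
    "load_model",
    "load_params",
    "dump_params",
    "rhs_second_order",
    "rhs_third_order",
]

MODEL_NAMES = ("second_order", "third_order")

# Parameter layout for the packed vector handed to the numeric kernels.  The
# order is load-bearing: `_engine` indexes into the packed vector positionally.
SECOND_ORDER_KEYS = (
    "C_m",          # membrane capacitance, µF/cm²
    "g_T", "E_T",   # T-type Ca conductance (mS/cm²) and reversal (mV)
    "g_L", "E_L",   # leak conductance and reversal
    "v_rev",        # modulating-synapse reversal potential, mV
    "I_ext",        # constant external current, µA/cm²
    "phi_h",        # temperature factor on the h gate
    "exp_T_m",      # activation exponent of the T current
    "m_vhalf", "m_k",           # m_inf(v) = 1/(1+exp(-(v-m_vhalf)/m_k))
    "h_vhalf", "h_k",           # h_inf(v) = 1/(1+exp((v-h_vhalf)/h_k))
    "tau_h_base", "tau_h_shift", "tau_h_k",
    # tau_h(v) = tau_h_base + h_inf(v) * exp((v+tau_h_shift)/tau_h_k)
)

THIRD_ORDER_KEYS = (
    "C_m",
    "g_L", "E_L",
    "g_Na", "E_Na",
    "g_K", "E_K",
    "g_T", "E_T",
    "v_rev",
    "I_ext",
    "phi_h", "phi_r",
    "exp_Na_m", "exp_K_n", "exp_T_p",
    "k_frac",                   # K gate slaved as n = k_frac * (1 - h)
    "m_vhalf", "m_k",           # Na activation (instantaneous)
    "h_vhalf", "h_k",           # Na inactivation steady state
    "ah_scale", "ah_vshift", "ah_k",    # tau_h = 1/(a_h + b_h)
    "bh_scale", "bh_vhalf", "bh_k",
    "p_vhalf", "p_k",           # T activation (instantaneous)
    "r_vhalf", "r_k",           # T inactivation steady state
    "tau_r_base", "tau_r_shift", "tau_r_k", "tau_r_scale",
    # tau_r(v) = tau_r_scale * (tau_r_base + exp(-(v+tau_r_shift)/tau_r_k))
)

_KEYSETS = {"second_order": SECOND_ORDER_KEYS, "third_order": THIRD_ORDER_KEYS}

V_PHYSIO = (-120.0, 60.0)  # physiological voltage range for validation, mV


# ---------------------------------------------------------------------------
# vector fields (written with numpy ufuncs: valid on scalars and arrays alike)
# ---------------------------------------------------------------------------

def _rhs2(v, h, s, P):
    """Second-order model: returns (dv/dt, dh/dt)."""
    (C_m, g_T, E_T, g_L, E_L, v_rev, I_ext, phi_h, exp_T_m,
     m_vhalf, m_k, h_vhalf, h_k, tau_h_base, tau_h_shift, tau_h_k) = P
    m_inf = 1.0 / (1.0 + np.exp(-(v - m_vhalf) / m_k))
    h_inf = 1.0 / (1.0 + np.exp((v - h_vhalf) / h_k))
    tau_h = tau_h_base + h_inf * np.exp((v + tau_h_shift) / tau_h_k)
    I_T = g_T * m_inf ** exp_T_m * h * (v - E_T)
    I_L = g_L * (v - E_L)
    dv = (-I_T - I_L + I_ext - s * (v - v_rev)) / C_m
    dh = phi_h * (h_inf - h) / tau_h
    return dv, dh


def _rhs3(v, h, r, s, P):
    """Third-order model: returns (dv/dt, dh/dt, dr/dt)."""
    (C_m, g_L, E_L, g_Na, E_Na, g_K, E_K, g_T, E_T, v_rev, I_ext,
     phi_h, phi_r, exp_Na_m, exp_K_n, exp_T_p, k_frac,
     m_vhalf, m_k, h_vhalf, h_k,
     ah_scale, ah_vshift, ah_k, bh_scale, bh_vhalf, bh_k,
     p_vhalf, p_k, r_vhalf, r_k,
     tau_r_base, tau_r_shift, tau_r_k, tau_r_scale) = P
    m_inf = 1.0 / (1.0 + np.exp(-(v - m_vhalf) / m_k))
    h_inf = 1.0 / (1.0 + np.exp((v - h_vhalf) / h_k))
    a_h = ah_scale * np.exp(-(v + ah_vshift) / ah_k)
    b_h = bh_scale / (1.0 + np.exp(-(v - bh_vhalf) / bh_k))
    tau_h = 1.0 / (a_h + b_h)
    p_inf = 1.0 / (1.0 + np.exp(-(v - p_vhalf) / p_k))
    r_inf = 1.0 / (1.0 + np.exp((v - r_vhalf) / r_k))
    tau_r = tau_r_scale * (tau_r_base + np.exp(-(v + tau_r_shift) / tau_r_k))
    n = k_frac * (1.0 - h)
    I_L = g_L * (v - E_L)
    I_Na = g_Na * m_inf ** exp_Na_m * h * (v - E_Na)
    I_K = g_K * n ** exp_K_n * (v - E_K)
    I_T = g_T * p_inf ** exp_T_p * r * (v - E_T)
    dv = (-I_L - I_Na - I_K - I_T + I_ext - s * (v - v_rev)) / C_m
    dh = phi_h * (h_inf - h) / tau_h
    dr = phi_r * (r_inf - r) / tau_r
    return dv, dh, dr


def rhs_second_order(x, s, params: "ModelParameters | dict") -> np.ndarray:
    """Evaluate the 2nd-order vector field at state ``x = (v, h)``.

    ``x`` may be a single state of shape ``(2,)`` or a batch ``(m, 2)``;
    ``s`` is the modulating conductance (scalar or length-``m``).
    """
    P = _as_pvec(params, "second_order")
    x = np.asarray(x, dtype=float)
    _check_finite(x)
    dv, dh = _rhs2(x[..., 0], x[..., 1], s, P)
    return np.stack(np.broadcast_arrays(dv, dh), axis=-1)


def rhs_third_order(x, s, params: "ModelParameters | dict") -> np.ndarray:
    """Evaluate the 3rd-order vector field at state ``x = (v, h, r)``."""
    P = _as_pvec(params, "third_order")
    x = np.asarray(x, dtype=float)
    _check_finite(x)
    dv, dh, dr = _rhs3(x[..., 0], x[..., 1], x[..., 2], s, P)
    return np.stack(np.broadcast_arrays(dv, dh, dr), axis=-1)


_STATE_NAMES = {
    "second_order": ("v", "h"),
    "third_order": ("v", "h", "r"),
}


def _check_finite(x: np.ndarray, model: str | None = None) -> None:
    if np.all(np.isfinite(x)):
        return
    bad = np.argwhere(~np.isfinite(np.atleast_2d(x)))
    comp = int(bad[0][-1])
    names = _STATE_NAMES.get(model or "", None)
    label = names[comp] if names and comp < len(names) else f"component {comp}"
    raise ValueError(f"non-finite state: {label} (index {comp}) is not finite")


def _as_pvec(params, model: str) -> tuple:
    if isinstance(params, ModelParameters):
        return params.pvec
    keys = _KEYSETS[model]
    missing = [k for k in keys if k not in params]
    if missing:
        raise KeyError(f"missing parameters for {model}: {missing}")
    return tuple(float(params[k]) for k in keys)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Full numeric parameterization of one model.

    ``values`` maps every key of the model's keyset to a float.  Invariants
    (positive capacitance, non-negative conductances, gate steady states in
    [0, 1] and positive time constants over the physiological voltage range)
    are checked at construction.
    """

    model: str
    values: dict = field(repr=False)

    def __post_init__(self):
        keys = _KEYSETS[self.model]
        unknown = sorted(set(self.values) - set(keys))
        if unknown:
            raise KeyError(
                f"unknown parameter(s) {unknown} for model '{self.model}'; "
                f"valid keys: {sorted(keys)}"
            )
        missing = [k for k in keys if k not in self.values]
        if missing:
            raise KeyError(f"missing parameter(s) for '{self.model}': {missing}")
        self._validate()

    def _validate(self) -> None:
        v = self.values
        if v["C_m"] <= 0:
            raise ValueError("C_m must be positive")
        for k in v:
            if k.startswith("g_") and v[k] < 0:
                raise ValueError(f"conductance {k} must be non-negative")
        vv = np.linspace(*V_PHYSIO, 181)
        for g_inf, tau in self._gate_tables(vv):
            if np.any((g_inf < 0) | (g_inf > 1)):
                raise ValueError("gate steady state leaves [0, 1]")
            if np.any(tau <= 0):
                raise ValueError("gate time constant must be positive")

    def _gate_tables(self, vv: np.ndarray):
        P = self.pvec
        if self.model == "second_order":
            s0 = np.zeros_like(vv)
            # evaluate via the rhs pieces: reconstruct h_inf / tau_h directly
            h_vhalf, h_k = self["h_vhalf"], self["h_k"]
            h_inf = 1.0 / (1.0 + np.exp((vv - h_vhalf) / h_k))
            tau_h = self["tau_h_base"] + h_inf * np.exp(
                (vv + self["tau_h_shift"]) / self["tau_h_k"])
            return [(h_inf, tau_h)]
        h_inf = 1.0 / (1.0 + np.exp((vv - self["h_vhalf"]) / self["h_k"]))
        a_h = self["ah_scale"] * np.exp(-(vv + self["ah_vshift"]) / self["ah_k"])
        b_h = self["bh_scale"] / (1.0 + np.exp(-(vv - self["bh_vhalf"]) / self["bh_k"]))
        tau_h = 1.0 / (a_h + b_h)
        r_inf = 1.0 / (1.0 + np.exp((vv - self["r_vhalf"]) / self["r_k"]))
        tau_r = self["tau_r_scale"] * (
            self["tau_r_base"] + np.exp(-(vv + self["tau_r_shift"]) / self["tau_r_k"]))
        return [(h_inf, tau_h), (r_inf, tau_r)]

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    @property
    def pvec(self) -> tuple:
        """Parameters packed in keyset order (consumed by the kernels)."""
        return tuple(float(self.values[k]) for k in _KEYSETS[self.model])

    @property
    def C_m(self) -> float:
        return self.values["C_m"]

    @property
    def v_rev(self) -> float:
        return self.values["v_rev"]


@dataclass(frozen=True)
class NeuronModel:
    """A parameterized relay-neuron vector field.

    Component 0 of the state is always the membrane voltage (mV); components
    ``1..n-1`` are gate probabilities.  This ordering is load-bearing: the
    linearization selects component 0 as the output and injects the modulating
    perturbation only into component 0.
    """

    name: str
    n: int
    params: ModelParameters

    @property
    def kind(self) -> int:
        """Engine dispatch code: the model order."""
        return self.n

    @property
    def C_m(self) -> float:
        return self.params.C_m

    @property
    def v_rev(self) -> float:
        return self.params.v_rev

    @property
    def gate_indices(self) -> tuple:
        return tuple(range(1, self.n))

    @property
    def state_names(self) -> tuple:
        return _STATE_NAMES[self.name]

    @property
    def pvec(self) -> np.ndarray:
        return np.asarray(self.params.pvec, dtype=float)

    def rhs(self, x, s) -> np.ndarray:
        """dx/dt at state(s) ``x`` with modulating conductance ``s``."""
        if self.name == "second_order":
            return rhs_second_order(x, s, self.params)
        return rhs_third_order(x, s, self.params)

    def gate_steady_state(self, v: float) -> np.ndarray:
        """Steady-state gate values at a fixed voltage (equilibrium manifold)."""
        p = self.params
        if self.name == "second_order":
            h_inf = 1.0 / (1.0 + np.exp((v - p["h_vhalf"]) / p["h_k"]))
            return np.atleast_1d(h_inf)
        h_inf = 1.0 / (1.0 + np.exp((v - p["h_vhalf"]) / p["h_k"]))
        r_inf = 1.0 / (1.0 + np.exp((v - p["r_vhalf"]) / p["r_k"]))
        return np.array([h_inf, r_inf])

    def check_gates(self, x, warn_tol: float = 1e-6, err_tol: float = 1e-2) -> None:
        """Diagnose gate values escaping [0, 1] (solver overshoot allowance).

        Gates are never clamped during integration; an excursion beyond
        ``warn_tol`` emits a warning, beyond ``err_tol`` raises.
        """
        import warnings

        g = np.atleast_2d(np.asarray(x, dtype=float))[:, 1:]
        excess = np.maximum(np.maximum(g - 1.0, -g), 0.0)
        worst = float(excess.max()) if g.size else 0.0
        if worst > err_tol:
            raise ValueError(f"gate left [0,1] by {worst:.3g} (> {err_tol:g})")
        if worst > warn_tol:
            warnings.warn(f"gate left [0,1] by {worst:.3g}", stacklevel=2)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def _fixture_path(name: str) -> Path:
    return Path(importlib.resources.files("relaybounds") / "fixtures" / f"{name}.toml")


def load_params(path: str | Path) -> dict:
    """Read a flat key/value parameter file (TOML syntax, comments allowed)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return {k: float(v) for k, v in data.items()}


def dump_params(values: dict, path: str | Path) -> None:
    """Write parameters back to a flat key/value file (round-trips values)."""
    lines = [f"{k} = {float(v)!r}" for k, v in values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(name: str, overrides: dict | None = None) -> NeuronModel:
    """Load a packaged model by name, optionally overriding parameters.

    Parameters
    ----------
    name : {"second_order", "third_order"}
    overrides : dict, optional
        Map of known parameter names to replacement values.  Unknown names
        raise a ``KeyError`` listing the valid keys.
    """
    if name not in MODEL_NAMES:
        raise KeyError(f"unknown model '{name}'; valid names: {list(MODEL_NAMES)}")
    values = load_params(_fixture_path(name))
    if overrides:
        unknown = sorted(set(overrides) - set(_KEYSETS[name]))
        if unknown:
            raise KeyError(
                f"unknown override(s) {unknown} for model '{name}'; "
                f"valid keys: {sorted(_KEYSETS[name])}"
            )
        values = {**values, **{k: float(v) for k, v in overrides.items()}}
    params = ModelParameters(model=name, values=values)
    return NeuronModel(name=name, n=2 if name == "second_order" else 3, params=params)
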