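"""Shared fixtures: the three canonical relay-neuron operating points.

Heavy stage results (linearization, threshold bisection, adjoint kernel) are
session-scoped so the suite computes them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from relaybounds import (OperatingPoint, critical_linearization, decision_kernel,
                         default_response_config, linearize, load_model,
                         omega_from_hz, threshold_current)


@pytest.fixture(scope="session")
def second_model():
    return load_model("second_order")


@pytest.fixture(scope="session")
def burst_model():
    return load_model("third_order", {"I_ext": -0.5})


@pytest.fixture(scope="session")
def tonic_model():
    return load_model("third_order", {"I_ext": 1.2})


#: canonical operating points (mirror the packaged sweep configs)
SECOND_POINT = OperatingPoint(S0=0.45, S1=0.05, omega=omega_from_hz(35.0),
                              alpha=11.9, lam=0.02, T_R_drive=10.0)
BURST_POINT = OperatingPoint(S0=0.10, S1=0.02, omega=omega_from_hz(20.0),
                             alpha=9.35, lam=0.02, T_R_drive=10.0)
TONIC_POINT = OperatingPoint(S0=0.10, S1=0.01, omega=omega_from_hz(12.0),
                             alpha=12.5, lam=0.02, T_R_drive=10.0)


@pytest.fixture(scope="session")
def second_stages(second_model):
    """(lin, thr, crit, kernel) of the 2nd-order model at its base S0."""
    return _stages(second_model, SECOND_POINT.S0)


@pytest.fixture(scope="session")
def burst_stages(burst_model):
    return _stages(burst_model, BURST_POINT.S0)


@pytest.fixture(scope="session")
def tonic_stages(tonic_model):
    return _stages(tonic_model, TONIC_POINT.S0)


def _stages(model, S0):
    cfg = default_response_config(model)
    lin = linearize(model, S0)
    thr = threshold_current(model, S0, config=cfg)
    crit = critical_linearization(model, thr.x_c, S0)
    kern = decision_kernel(model, thr.x_c, S0)
    return lin, thr, crit, kern


def sine_fit(t, y, omega):
    """Least-squares fit y ~ c0 + a sin(wt) + b cos(wt) -> (amp, phase, c0).

    ``phase`` is such that y ~ c0 + amp * sin(w t + phase).
    """
    X = np.column_stack([np.ones_like(t), np.sin(omega * t), np.cos(omega * t)])
    c0, a, b = np.linalg.lstsq(X, y, rcond=None)[0]
    return float(np.hypot(a, b)), float(np.arctan2(b, a)), float(c0)
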