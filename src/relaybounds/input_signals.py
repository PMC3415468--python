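"""Driving and modulating inputs of a relay neuron.

The driving input is a sparse train of excitatory delta pulses whose
inter-pulse intervals are ``T_R + Exp(lambda)`` (a refractory floor plus an
exponential tail); the modulating input is a slow sinusoidal inhibitory
conductance ``s(t) = S0 + S1 sin(omega t)`` with ``0 <= S1 <= S0`` so the
conductance never goes negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PulseTrain",
    "ModulatingSignal",
    "generate_pulse_train",
    "modulating_value",
    "interval_survival",
    "omega_from_hz",
    "hz_from_omega",
]


def omega_from_hz(f_hz: float) -> float:
    """Convert a frequency in Hz to angular frequency in rad/ms."""
    return 2.0 * np.pi * f_hz / 1000.0


def hz_from_omega(omega: float) -> float:
    return omega * 1000.0 / (2.0 * np.pi)


@dataclass(frozen=True)
class PulseTrain:
    """Driving-input event times with a common pulse height.

    ``times`` are strictly increasing (ms); every interval is at least the
    driving refractory floor ``T_R_drive``; the mean interval converges to
    ``T_R_drive + 1/lam``.
    """

    times: np.ndarray
    alpha: float            # pulse height, µA·ms/cm²
    T_R_drive: float        # refractory floor of the source, ms
    lam: float              # exponential rate, 1/ms
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and np.any(np.diff(t) < self.T_R_drive - 1e-12):
            raise ValueError("inter-pulse interval below the refractory floor")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("pulse times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def mean_interval(self) -> float:
        """Population mean interval ``T_R_drive + 1/lam``."""
        return self.T_R_drive + 1.0 / self.lam

    def shifted(self, dt: float) -> "PulseTrain":
        return PulseTrain(self.times + dt, self.alpha, self.T_R_drive,
                          self.lam, self.seed)

    # -- plain-text event-file dialect: two whitespace-separated columns
    #    (time_ms, height), '#' comments carry the generator parameters.
    def to_file(self, path: str | Path) -> None:
        hdr = (f"# pulse train: T_R_drive={self.T_R_drive!r} lam={self.lam!r} "
               f"seed={self.seed!r}\n# time_ms height\n")
        body = "".join(f"{float(t)!r} {float(self.alpha)!r}\n" for t in self.times)
        Path(path).write_text(hdr + body)

    @classmethod
    def from_file(cls, path: str | Path) -> "PulseTrain":
        meta = {"T_R_drive": 0.0, "lam": 1.0, "seed": None}
        times, heights = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k in meta:
                            meta[k] = None if v == "None" else float(v)
                continue
            if line:
                t, a = line.split()
                times.append(float(t))
                heights.append(float(a))
        alpha = heights[0] if heights else 0.0
        seed = meta["seed"]
        return cls(np.asarray(times), alpha, meta["T_R_drive"], meta["lam"],
                   None if seed is None else int(seed))


@dataclass(frozen=True)
class ModulatingSignal:
    """Sinusoidal modulating conductance ``s(t) = S0 + S1 sin(omega t)``."""

    S0: float       # DC offset, mS/cm²
    S1: float       # oscillation amplitude, mS/cm²
    omega: float    # angular frequency, rad/ms

    def __post_init__(self):
        if self.S0 < 0:
            raise ValueError("S0 must be non-negative")
        if not (0 <= self.S1 <= self.S0):
            raise ValueError("need 0 <= S1 <= S0 so the conductance stays >= 0")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")

    def value(self, t):
        return self.S0 + self.S1 * np.sin(self.omega * np.asarray(t, dtype=float))

    @property
    def period(self) -> float:
        return np.inf if self.omega == 0 else 2.0 * np.pi / self.omega

    @property
    def f_hz(self) -> float:
        return hz_from_omega(self.omega)


def modulating_value(sig: ModulatingSignal, t):
    """Evaluate ``s(t)``; vectorizes over ``t``."""
    return sig.value(t)


def generate_pulse_train(alpha: float, lam: float, T_R_drive: float,
                         duration: float,
                         seed: int | np.random.Generator | None = None,
                         t_start: float = 0.0) -> PulseTrain:
    """Draw a refractory-exponential pulse train on ``[t_start, t_start+duration]``.

    Intervals are i.i.d. ``T_R_drive + Exp(lam)``; the first pulse sits one
    full interval after ``t_start`` (no pulse at the origin, so a slowly
    driven neuron settles onto its steady-state orbit before the first event).
    Reproducible for a fixed integer seed.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if T_R_drive < 0:
        raise ValueError("T_R_drive must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mean = T_R_drive + 1.0 / lam
    n_guess = max(16, int(duration / mean * 1.5) + 8)
    times = []
    t = t_start
    while True:
        ivals = T_R_drive + rng.exponential(1.0 / lam, size=n_guess)
        for dt in ivals:
            t += dt
            if t > t_start + duration:
                return PulseTrain(np.asarray(times), alpha, T_R_drive, lam,
                                  seed if isinstance(seed, int) else None)
            times.append(t)


def interval_survival(lam: float, T_R_drive: float, tau) -> np.ndarray | float:
    """P(inter-pulse interval > tau) for the refractory-exponential law.

    Equals 1 for ``tau <= T_R_drive`` (the hard floor) and
    ``exp(-lam (tau - T_R_drive))`` beyond it.  Non-increasing and continuous
    in ``tau``.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    out = np.where(tau <= T_R_drive, 1.0, np.exp(-lam * np.maximum(tau - T_R_drive, 0.0)))
    return float(out) if out.ndim == 0 else out
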