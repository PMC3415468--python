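"""Run configuration: one YAML file fully describes an experiment.

Frequencies may be given in Hz (``f_hz`` / ``grid_hz``) — converted once at
parse time; all internal math uses rad/ms.  A config round-trips losslessly
through :func:`load_config` / :func:`dump_config`, and every command writes
its resolved config next to its outputs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .input_signals import omega_from_hz
from .model_core import MODEL_NAMES
from .reliability_bounds import OperatingPoint
from .simulator import ResponseConfig

__all__ = ["RunConfig", "load_config", "dump_config", "packaged_config",
           "PACKAGED_CONFIGS"]


@dataclass(frozen=True)
class RunConfig:
    """Model choice, input parameters, sweep spec and run settings."""

    model: str = "second_order"
    overrides: dict = field(default_factory=dict)
    S0: float = 0.45
    S1: float = 0.05
    f_hz: float = 35.0          # modulating frequency (Hz)
    alpha: float = 11.9
    lam: float = 0.02           # 1/ms
    T_R_drive: float = 10.0     # ms
    sweep_var: str | None = None
    sweep_grid: list = field(default_factory=list)      # in internal units
    sweep_grid_hz: list = field(default_factory=list)   # for omega sweeps
    n_trials: int = 20
    n_pulses: int = 200
    seed: int = 0
    spike_level: float | None = None    # None -> per-model default
    relay_window: float = 10.0
    burst_merge: float = 6.0
    dt: float | None = None
    out_dir: str = "relaybounds-out"

    def __post_init__(self):
        if self.model not in MODEL_NAMES:
            raise ValueError(
                f"config field 'model': unknown model '{self.model}', "
                f"expected one of {list(MODEL_NAMES)}")
        if self.sweep_var is not None and not (self.sweep_grid or self.sweep_grid_hz):
            raise ValueError("config field 'sweep_grid': empty sweep grid")
        if self.n_trials < 1 or self.n_pulses < 1:
            raise ValueError("config fields 'n_trials'/'n_pulses' must be >= 1")

    @property
    def omega(self) -> float:
        return omega_from_hz(self.f_hz)

    @property
    def point(self) -> OperatingPoint:
        return OperatingPoint(S0=self.S0, S1=self.S1, omega=self.omega,
                              alpha=self.alpha, lam=self.lam,
                              T_R_drive=self.T_R_drive)

    @property
    def grid(self) -> list:
        if self.sweep_grid_hz:
            return [omega_from_hz(f) for f in self.sweep_grid_hz]
        return list(self.sweep_grid)

    def response_config(self, model=None) -> ResponseConfig:
        from .simulator import default_response_config

        level = self.spike_level
        if level is None:
            from .model_core import load_model
            m = model if model is not None else load_model(self.model, self.overrides)
            level = default_response_config(m).spike_level
        return ResponseConfig(spike_level=level, relay_window=self.relay_window,
                              burst_merge=self.burst_merge)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config field(s) {unknown}; "
                         f"valid fields: {sorted(known)}")
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


PACKAGED_CONFIGS = (
    "second_order_omega", "second_order_S0", "second_order_lam",
    "third_order_bursting_omega", "third_order_bursting_S0",
    "third_order_bursting_lam",
    "third_order_tonic_omega", "third_order_tonic_S0", "third_order_tonic_lam",
)


def packaged_config(name: str) -> RunConfig:
    """Load one of the canonical packaged experiment configurations."""
    if name not in PACKAGED_CONFIGS:
        raise KeyError(f"unknown packaged config '{name}'; "
                       f"available: {list(PACKAGED_CONFIGS)}")
    path = importlib.resources.files("relaybounds") / "configs" / f"{name}.yaml"
    return load_config(path)
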