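# Canonical relaybounds experiment: S0 sweep for the third_order model.
# Frequencies in Hz; conductances mS/cm^2; currents uA/cm^2; times ms.
model: third_order
overrides:
  I_ext: 1.2
S0: 0.1
S1: 0.01
f_hz: 12.0
alpha: 12.5
lam: 0.02
T_R_drive: 10.0
n_trials: 12
n_pulses: 150
seed: 0
sweep_var: S0
sweep_grid:
- 0.08
- 0.1
- 0.12
spike_level: -45.0
relay_window: 20.0
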