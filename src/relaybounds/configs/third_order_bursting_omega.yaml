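# Canonical relaybounds experiment: omega sweep for the third_order model.
# Frequencies in Hz; conductances mS/cm^2; currents uA/cm^2; times ms.
model: third_order
overrides:
  I_ext: -0.5
S0: 0.1
S1: 0.02
f_hz: 20.0
alpha: 9.35
lam: 0.02
T_R_drive: 10.0
n_trials: 12
n_pulses: 150
seed: 0
sweep_var: omega
sweep_grid_hz:
- 10.0
- 16.0
- 25.0
- 35.0
spike_level: -45.0
relay_window: 20.0
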