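# Canonical relaybounds experiment: S0 sweep for the second_order model.
# Frequencies in Hz; conductances mS/cm^2; currents uA/cm^2; times ms.
model: second_order
overrides: {}
S0: 0.45
S1: 0.05
f_hz: 35.0
alpha: 11.9
lam: 0.02
T_R_drive: 10.0
n_trials: 20
n_pulses: 200
seed: 0
sweep_var: S0
sweep_grid:
- 0.4
- 0.45
- 0.5
- 0.55
- 0.6
- 0.65
spike_level: -30.0
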