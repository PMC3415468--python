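# Second-order relay-neuron model: low-threshold T-type calcium current +
# leak.  Functional forms and kinetics follow the Wang & Rinzel (1992)
# post-inhibitory-rebound thalamic cell (also the basis of the Manor et al.
# 1997 inferior-olive subthreshold-oscillation model).  Units: mV, ms,
# uA/cm^2, mS/cm^2, uF/cm^2.

C_m = 1.0         # uF/cm^2; membrane capacitance (Wang-Rinzel 1992)
g_T = 1.0         # mS/cm^2; maximal T-type Ca conductance (Wang-Rinzel 1992)
E_T = 120.0       # mV; calcium reversal potential (Wang-Rinzel 1992)
g_L = 0.15        # mS/cm^2; leak conductance (Wang-Rinzel 1992)
E_L = -60.0       # mV; leak reversal (Wang-Rinzel 1992)
v_rev = -85.0     # mV; modulating (GABAergic) synaptic reversal potential
I_ext = 0.0       # uA/cm^2; no bias current; the modulating conductance
                  # (S0 >= ~0.25 toward v_rev) hyperpolarizes the cell onto its
                  # single stable relay equilibrium (see docs/methods.md)
phi_h = 2.0       # temperature correction on the h gate (Wang-Rinzel 1992)
exp_T_m = 3.0     # activation exponent: I_T = g_T m_inf^3 h (v - E_T)

# T-current activation m_inf(v) = 1/(1+exp(-(v - m_vhalf)/m_k))
m_vhalf = -65.0   # mV (Wang-Rinzel 1992)
m_k = 7.8         # mV (Wang-Rinzel 1992)

# T-current inactivation h_inf(v) = 1/(1+exp((v - h_vhalf)/h_k))
h_vhalf = -81.0   # mV (Wang-Rinzel 1992)
h_k = 11.0        # mV (Wang-Rinzel 1992)

# tau_h(v) = tau_h_base + h_inf(v) * exp((v + tau_h_shift)/tau_h_k), ms
tau_h_base = 20.0     # ms (Wang-Rinzel 1992)
tau_h_shift = 162.3   # mV (Wang-Rinzel 1992)
tau_h_k = 17.8        # mV (Wang-Rinzel 1992)
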