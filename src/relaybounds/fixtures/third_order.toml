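# Third-order thalamocortical relay-neuron model: leak + fast sodium +
# delayed-rectifier potassium (gate slaved to sodium inactivation) +
# low-threshold T-type calcium current.  Equations and parameters follow the
# reduced thalamic cell of Rubin & Terman (2004), as used in later relay
# studies.  Depolarized (tonic) operation gives one spike per pulse;
# hyperpolarized operation gives a burst per pulse.  Units: mV, ms, uA/cm^2,
# mS/cm^2, uF/cm^2.

C_m = 1.0        # uF/cm^2 (Rubin-Terman 2004)
g_L = 0.05       # mS/cm^2; leak conductance (Rubin-Terman 2004)
E_L = -70.0      # mV (Rubin-Terman 2004)
g_Na = 3.0       # mS/cm^2; fast sodium (Rubin-Terman 2004)
E_Na = 50.0      # mV (Rubin-Terman 2004)
g_K = 5.0        # mS/cm^2; delayed rectifier (Rubin-Terman 2004)
E_K = -90.0      # mV (Rubin-Terman 2004)
g_T = 5.0        # mS/cm^2; T-type calcium (Rubin-Terman 2004)
E_T = 0.0        # mV; effective Ca reversal (Rubin-Terman 2004)
v_rev = -85.0    # mV; modulating (GABAergic) synaptic reversal potential
I_ext = 0.0      # uA/cm^2; bias current; the tonic/bursting run fixtures
                 # override this (see configs and docs/methods.md)
phi_h = 1.0      # temperature factor, h gate (Rubin-Terman 2004)
phi_r = 1.0      # temperature factor, r gate (Rubin-Terman 2004)

exp_Na_m = 3.0   # I_Na = g_Na m_inf^3 h (v - E_Na)
exp_K_n = 4.0    # I_K  = g_K n^4 (v - E_K)
exp_T_p = 2.0    # I_T  = g_T p_inf^2 r (v - E_T)
k_frac = 0.75    # K gate slaved to Na inactivation: n = 0.75 (1 - h)

# Na activation (instantaneous): m_inf(v) = 1/(1+exp(-(v - m_vhalf)/m_k))
m_vhalf = -37.0  # mV (Rubin-Terman 2004)
m_k = 7.0        # mV (Rubin-Terman 2004)

# Na inactivation: h_inf(v) = 1/(1+exp((v - h_vhalf)/h_k))
h_vhalf = -41.0  # mV (Rubin-Terman 2004)
h_k = 4.0        # mV (Rubin-Terman 2004)

# tau_h(v) = 1/(a_h(v) + b_h(v));
# a_h = ah_scale exp(-(v+ah_vshift)/ah_k), b_h = bh_scale/(1+exp(-(v-bh_vhalf)/bh_k))
ah_scale = 0.128   # (Rubin-Terman 2004)
ah_vshift = 46.0   # mV
ah_k = 18.0        # mV
bh_scale = 4.0
bh_vhalf = -23.0   # mV
bh_k = 5.0         # mV

# T activation (instantaneous): p_inf(v) = 1/(1+exp(-(v - p_vhalf)/p_k))
p_vhalf = -60.0  # mV (Rubin-Terman 2004)
p_k = 6.2        # mV (Rubin-Terman 2004)

# T inactivation: r_inf(v) = 1/(1+exp((v - r_vhalf)/r_k))
r_vhalf = -84.0  # mV (Rubin-Terman 2004)
r_k = 4.0        # mV (Rubin-Terman 2004)

# tau_r(v) = tau_r_scale * (tau_r_base + exp(-(v + tau_r_shift)/tau_r_k)), ms
tau_r_base = 28.0    # ms (Rubin-Terman 2004)
tau_r_shift = 25.0   # mV
tau_r_k = 10.5       # mV
tau_r_scale = 0.4    # dimensionless (Rubin-Terman 2004)
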