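# Methods

`relaybounds` studies how reliably a thalamic-type relay neuron transmits a
sparse excitatory pulse train ("driving input") under a slow sinusoidal
inhibitory conductance ("modulating input"), and computes closed-form lower
and upper bounds on that reliability from linearized system properties.
This note records the model, the derivations behind each stage, the numeric
choices, and the limits of what the tests demonstrate.

## Models

Both neuron models are conductance-based vector fields
`C_m v' = -Σ I_ion + I_ext - s(t)(v - v_rev) + u(t)`, with gates relaxing as
`x' = φ (x_inf(v) - x)/τ_x(v)`. The first state component is always the
voltage; this ordering is load-bearing for the linearization (input and
output both couple to component 0).

* **`second_order`** — voltage plus the inactivation gate `h` of a
  low-threshold T-type calcium current, `I_T = g_T m_inf³(v) h (v - E_T)`,
  with leak. Kinetics and parameters follow the Wang–Rinzel
  post-inhibitory-rebound thalamic cell (fixture
  `fixtures/second_order.toml`, one citation comment per value). With
  `I_ext = 0` the modulating conductance itself (reversal −85 mV)
  hyperpolarizes the cell onto a single stable equilibrium for
  `S0 ∈ [0.3, 0.8]` mS/cm²; at lower `S0` the model is bistable or
  oscillatory and the relay analysis does not apply (the equilibrium finder
  reports this).
* **`third_order`** — the Rubin–Terman reduced thalamocortical cell: leak,
  fast sodium (`m` instantaneous, inactivation `h`), delayed-rectifier
  potassium with its gate slaved as `n = 0.75(1-h)`, and a T-type calcium
  current with slow inactivation `r`. Two canonical operating modes set by
  the bias current: **tonic** (`I_ext = +1.2` µA/cm², rest ≈ −70 mV,
  `r ≈ 0.03`, one spike per suprathreshold pulse) and **bursting**
  (`I_ext = −0.5`, rest ≈ −83 mV, `r ≈ 0.4`, a compact 2–6-spikelet burst
  per pulse).

All units package-wide: mV, ms, µA/cm², mS/cm², µF/cm². A driving pulse is
an ideal delta of area `alpha` (µA·ms/cm²): it jumps the voltage by
`alpha/C_m` and leaves gates unchanged (verified against narrow rectangular
pulses of equal area).

## Inputs

Driving pulses arrive with i.i.d. intervals `T_R + Exp(λ)` — a refractory
floor plus an exponential tail; the first pulse sits one full interval after
the origin. The modulating conductance is `s(t) = S0 + S1 sin(ωt)` with
`0 ≤ S1 ≤ S0`. Frequencies are accepted in Hz at the config layer and
converted once (`ω = 2πf/1000` rad/ms).

## Reliability pipeline

Empirical reliability is the fraction of pulses followed by a successful
response (a spike, or a burst merged into one response) within the relay
window. The analytic bracket composes four stages:

1. **Equilibrium and linearization.** At equilibrium every gate sits on its
   steady-state curve, so equilibria reduce to a scalar root-find in `v`
   (dense sign-change scan + Brent; multiple roots are an error — the
   framework requires a "stable neuron"). The Jacobian `A` is central
   finite differences (adaptive relative step 1e-6); the input direction is
   `B = -(v_eq - v_rev)/C_m · e₁` and the output `C = e₁ᵀ`. The transfer
   gain `G(jω) = C(jωI - A)⁻¹B` is a low-pass filter; the forced
   steady-state orbit has per-component amplitude `S1|H_k|`, phase
   `∠H_k`, with `H = (jωI - A)⁻¹B`.

2. **Threshold structure.** `I_th` is the smallest pulse height that
   elicits a response from the settled equilibrium (bisection, tolerance
   1e-3 in `alpha` units); `v_th = v_eq + I_th/C_m`; the critical point
   `x_c` is the post-jump state at threshold — the point on the
   sub/supra-threshold separatrix that near-threshold trajectories from the
   orbit actually visit. The Jacobian at `x_c` has one positive real
   eigenvalue (trajectories divert from the separatrix); this is checked,
   and a complex leading eigenvalue triggers a numerically scanned
   fallback interval, flagged as such.

3. **Success-phase interval.** A pulse at modulating phase φ succeeds iff
   the post-jump state falls on the supra-threshold side. Linearizing the
   decision dynamics *along the critical trajectory* from `x_c` gives the
   criterion
   `(alpha - I_th)/C_m + S1 |g(ω)| sin(φ + ψ) > 0`, with
   `g(ω) = q₀·H(ω) + ∫ K(τ) e^{jωτ} dτ`:
   `q₀` is the adjoint success functional at the pulse instant and
   `K(τ) = q(τ)·B(x(τ))` weights the modulating input still acting while
   the trajectory diverts. `q(τ)` comes from one integration of the
   variational system along the critical trajectory (LSODA, rtol 1e-8,
   horizon 60 ms), taking the dominant left singular direction of the
   fundamental matrix. When the Jacobian is frozen at `x_c` this reduces
   exactly to the classical form `q₀ ∝ w₁` (leading left eigenvector) and
   `K(τ) ∝ e^{-λ₁τ}`; carrying the time variation removes a systematic
   ~0.15 rad phase shift visible in the slow tonic mode (leading eigenvalue
   ≈ 0.2/ms, so the decision integrates the input over ~5 ms during which
   both Jacobian and input coupling change). The only validation authority
   for this stage is the brute-force phase scan (simulate one pulse at each
   of 64 phases on the settled orbit); agreement is ≥ 62/64 on 3×3
   (frequency, pulse-height) grids for all three fixtures.
   `P_S = P(X ∈ S)` is the interval length over 2π (pulse phases are
   uniform relative to the modulating cycle).

4. **Refractory bracket and bounds.** After a successful response the state
   needs `T_ref` to return to the orbit tube; after an unsuccessful one an
   unknown `T_ref_u ∈ [0, T_ref]`. With the interval-survival probability
   `p = P(T > T_ref) = exp(-λ(T_ref - T_R)⁺)`, bracketing `T_ref_u` by its
   extremes gives `P(X∈T) ∈ [p, 1/(1 + P_S(1-p))]` and

   `R_lb = P_S · p`,  `R_ub = P_S / (1 + P_S (1 - p))`.

   Limiting cases: sparse pulses collapse both to `P_S`; `T_ref ≤ T_R`
   collapses the bracket; `P_S = 1` with dense pulses drives `R_ub → 1/2`
   (each success censors exactly one following pulse). A renewal
   Monte-Carlo with the same per-pulse recursion is the oracle for the
   algebra.

`T_ref` is measured by a two-pulse protocol (bisection on the lag of a
second identical pulse, tolerance 0.1 ms). The bounds use a *preconditioned*
variant — four prior pulses at the tested lag — because slow gates
accumulate over successive responses and the steady-state refractory can
exceed the isolated two-pulse one (in the tonic fixture by up to ~50%).
For `alpha ≤ I_th` (successes then exist only at favourable phases) the
protocol probes at `1.01·I_th`; `T_ref` is largest near threshold, which
widens but never invalidates the bracket.

## Simulation engine

The production integrator is a fixed-step classical RK4 (numba-compiled)
with pulse times aligned to step boundaries, so no step ever crosses a
delta pulse — the jump is applied between steps exactly as a solver restart
would. Steps: 0.025 ms (2nd order), 0.01 ms (3rd order). These models are
only mildly stiff between spikes, and the spike upstrokes are resolved at
these steps; correctness is enforced by a trajectory cross-check against
scipy's LSODA and by the robustness requirement that halving the step flips
fewer than one relay decision per 10³ pulses. Spike detection happens
in-kernel as upward crossings of a fixed level, linearly interpolated; a
delta jump across the level counts only when the voltage keeps rising
afterwards (a jump landing on the falling flank of a previous spike is not
a new response). Simulations start on the analytic orbit and additionally
discard a warm-up of max(5 modulating periods, 500 ms).

Detection levels are per-model: −30 mV (2nd order; its calcium spikes peak
at −4..−1 mV) and −45 mV (3rd order; burst spikelets peak near −35 mV).
Relay windows cover the success latency (~`ln(·)/λ₁` after the pulse):
10 ms and 20 ms respectively; the intra-burst merge interval is 6 ms, below
both windows, and merges the 2–6 ms spikelet gaps of a burst into one
successful response.

## Canonical study conditions

Packaged configs (`relaybounds/configs/*.yaml`) freeze one operating point
per fixture and the sweep grids:

| fixture | S0 | S1 | f | alpha | λ | T_R |
|---|---|---|---|---|---|---|
| second_order | 0.45 | 0.05 | 35 Hz | 11.9 | 0.02/ms | 10 ms |
| third_order bursting | 0.10 | 0.02 | 20 Hz | 9.35 | 0.02/ms | 10 ms |
| third_order tonic | 0.10 | 0.01 | 12 Hz | 12.5 | 0.02/ms | 10 ms |

`alpha` sits just above the zero-modulation threshold (`I_th` ≈ 11.65,
9.07, 12.42 respectively), inside the band `I_th ± S1·G_eff` where the
modulating phase decides relay — the regime the analysis is about. The mean
driving interval (60 ms, ≈ 17 Hz) is sparse relative to the membrane
dynamics but dense relative to `T_ref`, so the bracket is informative. The
frequency sweep of the 2nd-order model runs 15–100 Hz: the beta-to-gamma
band relevant to basal-ganglia/thalamus modulation, and the band above this
fixture's mild subthreshold resonance (~15 Hz) where the gain is decaying
and reliability rises with frequency. `S0` sweeps stay inside each model's
single-equilibrium band; `S1` is kept at ≤ 11% of `S0` so the small-signal
orbit is accurate (orbit amplitude ≈ 0.9 mV against a ~10 mV distance to
threshold) and `S0 - S1 ≥ 0` holds with margin. The driving floor
`T_R = 10 ms` (≈ cortical-afferent refractoriness) also suppresses paired
pulse summation, which the per-pulse framework does not model.

Sweep sizes: 20 trials × 200 pulses per grid point (2nd order), 12 × 150
(3rd order, reduced grids of 3–4 points per variable).

## What the tests do and do not show

The synthetic conditions are exactly the model's own assumptions: ideal
delta pulses, a clean sinusoidal conductance, no channel noise, no
spatial structure, no synaptic kinetics beyond the multiplicative
conductance. Passing containment under these conditions validates the
*derivation and implementation*, not the biological fidelity of the bounds
for real thalamic neurons, where driving EPSPs have finite width, the
modulating input is an ensemble of stochastic IPSPs, and thresholds drift.

Known limitations, observed and by design:

* The bracket can fail when `alpha` is far above threshold while pulses are
  dense: a pulse can then succeed *before* the state is back in the orbit
  tube, successive responses accumulate slow-gate adaptation, and the
  effective refractory exceeds any single-response measurement. The
  preconditioned `T_ref` absorbs the moderate version of this; the extreme
  version (continuous adapted firing) is outside the framework.
* The analytic `P_S` degrades when `S1·|G|` approaches the distance to
  threshold (linearization regime); a warning fires on large orbit
  amplitudes.
* `T_ref_u` after an unsuccessful response is only bracketed, never
  computed — that is the entire reason the result is a pair of bounds
  rather than a point prediction.
* The spontaneous-firing adjustment `R' = R - (T_R + 1/λ)/T_noise` is an
  explicit approximation (worst case: every noise response displaces one
  driving relay); it reduces to the unadjusted bounds for rare noise and
  goes negative for frequent noise, and is never clamped.

## Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning (one child per trial/grid point).
Every CLI run writes its resolved config beside its outputs; re-running a
config reproduces outputs byte-for-byte. `scripts/acceptance.py --seed N`
re-derives every reported quantity from scratch at the canonical study
conditions.
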