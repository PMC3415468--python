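"""Simulation engine, response detection, empirical reliability."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from relaybounds import (ModulatingSignal, PulseTrain, ResponseConfig,
                         apply_pulse_jump, default_response_config,
                         detect_responses, empirical_reliability, simulate)
from relaybounds.linear_analysis import find_equilibrium
from tests.conftest import SECOND_POINT


class TestPulseJump:
    def test_zero_height_is_identity(self):
        x = np.array([-70.0, 0.3])
        np.testing.assert_array_equal(apply_pulse_jump(x, 0.0, 1.0), x)

    def test_height_equal_to_capacitance_gives_one_mV(self):
        x = apply_pulse_jump(np.array([-70.0, 0.3]), 2.0, 2.0)
        assert x[0] == -69.0
        assert x[1] == 0.3

    def test_mollified_delta_converges_to_jump(self, second_model):
        """A narrow rectangular current pulse of equal area approaches the
        instantaneous jump as its width shrinks."""
        S0, alpha = 0.45, 8.0
        x_eq = find_equilibrium(second_model, S0)
        target = apply_pulse_jump(x_eq, alpha, second_model.C_m)

        def end_state(width):
            def rhs(t, x):
                d = second_model.rhs(x, S0)
                d[0] += (alpha / width) / second_model.C_m
                return d
            sol = solve_ivp(rhs, (0, width), x_eq, rtol=1e-10, atol=1e-12)
            return sol.y[:, -1]

        err = [np.linalg.norm(end_state(w) - target) for w in (1.0, 0.1, 0.01)]
        # first-order convergence in the pulse width
        assert err[1] < 0.15 * err[0]
        assert err[2] < 0.15 * err[1]


class TestDetectResponses:
    CFG = ResponseConfig(spike_level=0.0, relay_window=12.0, burst_merge=10.0)

    def test_hand_built_event_list_gives_two_thirds(self):
        pulses = np.array([100.0, 200.0, 300.0])
        spikes = np.array([103.0, 304.0])
        _, flags, spont = detect_responses(spikes, pulses, self.CFG)
        assert flags.tolist() == [True, False, True]
        assert spont.size == 0

    def test_burst_of_four_spikes_counts_once(self):
        pulses = np.array([100.0])
        spikes = 103.0 + 4.0 * np.arange(4)
        responses, flags, _ = detect_responses(spikes, pulses, self.CFG)
        assert flags.tolist() == [True]
        assert sum(1 for _, k in responses if k == "successful") == 1

    def test_spike_just_outside_window_not_attributed(self):
        pulses = np.array([100.0])
        _, flags, spont = detect_responses(np.array([112.0001]), pulses, self.CFG)
        assert flags.tolist() == [False]
        assert spont.size == 1  # orphan response is reported, not dropped

    def test_response_attributed_to_latest_preceding_pulse(self):
        pulses = np.array([100.0, 108.0])
        _, flags, _ = detect_responses(np.array([109.0]), pulses, self.CFG)
        assert flags.tolist() == [False, True]

    def test_merge_must_be_shorter_than_window(self):
        with pytest.raises(ValueError):
            ResponseConfig(relay_window=10.0, burst_merge=10.0)


class TestSimulate:
    def test_no_pulses_no_responses_and_periodic_orbit(self, second_model):
        """Stable neuron: alpha=0 gives no spikes; the trajectory settles on
        an orbit with the modulating period."""
        sig = ModulatingSignal(0.45, 0.05, SECOND_POINT.omega)
        res = simulate(second_model, None, sig, 3 * sig.period,
                       config=default_response_config(second_model))
        assert res.spike_times.size == 0
        v, t = res.states[:, 0], res.t
        period_pts = int(round(sig.period / (t[1] - t[0])))
        lastper = v[-period_pts:]
        prevper = v[-2 * period_pts:-period_pts]
        np.testing.assert_allclose(lastper, prevper, atol=5e-3)

    def test_far_above_threshold_every_pulse_relayed(self, second_model):
        """With alpha far above threshold and gaps exceeding the refractory
        period, every pulse is relayed."""
        sig = ModulatingSignal(0.45, 0.05, SECOND_POINT.omega)
        times = 400.0 * np.arange(1, 21)
        train = PulseTrain(times, 25.0, 10.0, 0.02)
        res = simulate(second_model, train, sig, times[-1] + 100.0,
                       config=default_response_config(second_model),
                       record=False)
        assert res.relay_flags.all() and res.n_pulses == 20

    def test_far_below_threshold_nothing_relayed(self, second_model):
        sig = ModulatingSignal(0.45, 0.05, SECOND_POINT.omega)
        mean, sd, _ = empirical_reliability(
            second_model, sig, alpha=3.0, lam=0.02, T_R_drive=10.0,
            n_trials=3, seed=22, n_pulses=40,
            config=default_response_config(second_model))
        assert mean == 0.0 and sd == 0.0

    def test_time_translation_invariance(self, second_model):
        """Shifting pulses by a whole modulating period leaves flags fixed."""
        sig = ModulatingSignal(0.45, 0.05, SECOND_POINT.omega)
        cfg = default_response_config(second_model)
        dt = 0.025
        rng = np.random.default_rng(17)
        times = np.sort(rng.uniform(50, 4000, size=40))
        times = times[np.diff(np.concatenate(([0.0], times))) > 10]
        shift = round(3 * sig.period / dt) * dt
        res0 = simulate(second_model, PulseTrain(times, 11.9, 10.0, 0.02),
                        sig, 4500.0, config=cfg, dt=dt, record=False)
        res1 = simulate(second_model, PulseTrain(times + shift, 11.9, 10.0, 0.02),
                        sig, 4500.0 + shift, config=cfg, dt=dt, record=False)
        np.testing.assert_array_equal(res0.relay_flags, res1.relay_flags)

    def test_step_halving_changes_few_relay_events(self, second_model):
        """Halving dt flips < 1 relay decision per 10^3 pulses."""
        from relaybounds.input_signals import generate_pulse_train
        sig = ModulatingSignal(0.45, 0.05, SECOND_POINT.omega)
        cfg = default_response_config(second_model)
        duration = 1000 * 60.0
        train = generate_pulse_train(11.9, 0.02, 10.0, duration, seed=33)
        flags = []
        for dt in (0.025, 0.0125):
            res = simulate(second_model, train, sig, duration, config=cfg,
                           dt=dt, record=False)
            flags.append(res.relay_flags)
        n_flips = int(np.sum(flags[0] != flags[1]))
        assert n_flips <= 1

    def test_matches_variable_step_reference_solver(self, second_model):
        """Fixed-step engine vs scipy LSODA on a driven segment."""
        S0, S1, om, alpha = 0.45, 0.05, SECOND_POINT.omega, 11.0
        x_eq = find_equilibrium(second_model, S0)
        train = PulseTrain(np.array([20.0]), alpha, 0.0, 1.0)
        sig = ModulatingSignal(S0, S1, om)
        res = simulate(second_model, train, sig, 120.0, x0=x_eq, warmup=0.0,
                       config=default_response_config(second_model),
                       record_dt=0.1)

        def rhs(t, x):
            return second_model.rhs(x, S0 + S1 * np.sin(om * t))

        s1 = solve_ivp(rhs, (0, 20.0), x_eq, rtol=1e-10, atol=1e-12)
        x_jump = apply_pulse_jump(s1.y[:, -1], alpha, second_model.C_m)
        s2 = solve_ivp(rhs, (20.0, 120.0), x_jump, rtol=1e-10, atol=1e-12,
                       dense_output=True)
        tt = np.arange(25.0, 120.0, 5.0)
        v_ref = s2.sol(tt)[0]
        v_eng = np.interp(tt, res.t, res.states[:, 0])
        # the trajectory crosses a spike; compare where the flow is tame
        tame = np.abs(np.gradient(v_ref, tt)) < 5.0
        np.testing.assert_allclose(v_eng[tame], v_ref[tame], atol=0.1)

    def test_rerun_is_deterministic(self, second_model):
        sig = ModulatingSignal(0.45, 0.05, SECOND_POINT.omega)
        cfg = default_response_config(second_model)
        a = empirical_reliability(second_model, sig, 11.9, 0.02, 10.0,
                                  n_trials=2, seed=5, n_pulses=30, config=cfg)
        b = empirical_reliability(second_model, sig, 11.9, 0.02, 10.0,
                                  n_trials=2, seed=5, n_pulses=30, config=cfg)
        np.testing.assert_array_equal(a[2], b[2])


def test_stable_neuron_audit_all_fixtures(second_model, burst_model, tonic_model):
    """With no driving pulses none of the fixtures ever spikes."""
    for model, S0, S1 in [(second_model, 0.45, 0.05), (burst_model, 0.10, 0.02),
                          (tonic_model, 0.10, 0.01)]:
        sig = ModulatingSignal(S0, S1, SECOND_POINT.omega)
        res = simulate(model, None, sig, 2000.0,
                       config=default_response_config(model), record=False)
        assert res.spike_times.size == 0
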