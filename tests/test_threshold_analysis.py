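"""Threshold structure: I_th, T_ref, critical point, success-phase interval."""

import numpy as np
import pytest

from relaybounds import (ModulatingSignal, PulseTrain, critical_linearization,
                         default_response_config, phase_scan, prob_success,
                         refractory_period, simulate, success_phase_interval,
                         threshold_current)
from relaybounds.simulator import _group_spikes
from relaybounds.threshold_analysis import SuccessPhaseInterval, vth_slope
from tests.conftest import SECOND_POINT


class TestThresholdCurrent:
    def test_bisection_contract(self, second_model, second_stages):
        """A pulse just above I_th succeeds, just below fails."""
        _, thr, _, _ = second_stages
        cfg = default_response_config(second_model)
        from relaybounds.threshold_analysis import _single_pulse_success
        assert _single_pulse_success(second_model, 0.45, thr.I_th + 2e-3,
                                     cfg, None, 400.0)
        assert not _single_pulse_success(second_model, 0.45, thr.I_th - 2e-3,
                                         cfg, None, 400.0)

    def test_threshold_voltage_is_jump_landing(self, second_stages):
        lin, thr, _, _ = second_stages
        assert thr.v_th == pytest.approx(lin.v_eq + thr.I_th, abs=1e-9)
        assert thr.x_c[0] == thr.v_th

    def test_no_relay_regime_raises(self, second_model):
        with pytest.raises(RuntimeError, match="alpha"):
            threshold_current(second_model, 0.45, alpha_max=2.0)

    def test_tonic_and_bursting_thresholds_differ(self, burst_stages,
                                                  tonic_stages):
        assert burst_stages[1].I_th != pytest.approx(tonic_stages[1].I_th,
                                                     rel=0.1)

    def test_json_round_trip(self, second_stages):
        import json
        d = json.loads(second_stages[1].to_json())
        assert d["I_th"] == second_stages[1].I_th


@pytest.fixture(scope="module")
def tref(second_model):
    return refractory_period(second_model, 0.45, 14.0,
                             config=default_response_config(second_model))


class TestRefractoryPeriod:
    def test_half_lag_fails_double_lag_succeeds(self, second_model, tref):
        cfg = default_response_config(second_model)
        sig = ModulatingSignal(0.45, 0.0, 0.0)

        def second_pulse_ok(lag):
            train = PulseTrain(np.array([0.0, lag]), 14.0, 0.0, 1.0)
            res = simulate(second_model, train, sig, lag + 400.0, config=cfg,
                           warmup=0.0, record=False)
            groups = _group_spikes(np.sort(res.spike_times), cfg.burst_merge)
            return any(g[0] > lag for g in groups[1:])

        assert not second_pulse_ok(tref / 2)
        assert second_pulse_ok(2 * tref)

    def test_subthreshold_first_pulse_rejected(self, second_model,
                                               second_stages):
        with pytest.raises(RuntimeError, match="alpha"):
            refractory_period(second_model, 0.45,
                              second_stages[1].I_th - 1.0,
                              config=default_response_config(second_model))

    def test_smooth_in_pulse_height(self, second_model):
        """T_ref varies smoothly (no bisection chatter) along an alpha grid."""
        cfg = default_response_config(second_model)
        alphas = [13.0, 14.0, 15.0, 16.0]
        trefs = [refractory_period(second_model, 0.45, a, config=cfg, tol=0.05)
                 for a in alphas]
        assert all(b < a for a, b in zip(trefs, trefs[1:]))  # stronger pulse recovers sooner
        steps = np.abs(np.diff(trefs))
        assert steps.max() < 30.0

    def test_preconditioning_never_shortens(self, tonic_model):
        cfg = default_response_config(tonic_model)
        t2 = refractory_period(tonic_model, 0.12, 12.5, config=cfg)
        tp = refractory_period(tonic_model, 0.12, 12.5, config=cfg,
                               n_precondition=4)
        assert tp >= t2 - 0.2


class TestCriticalLinearization:
    def test_eigendecomposition_reconstructs_jacobian(self, second_stages):
        _, _, crit, _ = second_stages
        M_rec = crit.W @ np.diag(crit.eigenvalues) @ crit.W_left
        np.testing.assert_allclose(M_rec.real, crit.M, atol=1e-10)
        np.testing.assert_allclose(crit.W_left @ crit.W, np.eye(len(crit.M)),
                                   atol=1e-10)

    @pytest.mark.parametrize("stages", ["second_stages", "burst_stages",
                                        "tonic_stages"])
    def test_leading_eigenvalue_positive_real(self, stages, request):
        crit = request.getfixturevalue(stages)[2]
        assert crit.lambda1_real
        assert crit.eigenvalues[0].real > 0

    def test_crossing_flips_leading_mode_coefficient(self, second_model,
                                                     second_stages):
        """States just across the hypersurface have opposite lambda1-mode
        signs, and trajectories diverge accordingly."""
        _, thr, crit, _ = second_stages
        w1 = crit.W_left[0].real
        w1 = w1 if w1[0] > 0 else -w1
        for sgn in (+1, -1):
            x = thr.x_c + sgn * 0.05 * np.array([1.0, 0.0])
            assert np.sign(w1 @ (x - thr.x_c)) == sgn


class TestSuccessPhaseInterval:
    def test_no_modulation_full_or_empty(self, second_model, second_stages):
        lin, thr, crit, kern = second_stages
        sig0 = ModulatingSignal(0.45, 0.0, 0.2)
        full = success_phase_interval(second_model, lin, thr, sig0,
                                      thr.I_th + 1.0, crit=crit, kernel=kern)
        empty = success_phase_interval(second_model, lin, thr, sig0,
                                       thr.I_th - 1.0, crit=crit, kernel=kern)
        assert full.full and prob_success(full) == 1.0
        assert empty.empty and prob_success(empty) == 0.0

    def test_interval_proportionality(self):
        iv = SuccessPhaseInterval(start=1.0, width=np.pi)
        assert prob_success(iv) == 0.5

    def test_wrapped_interval_membership(self):
        iv = SuccessPhaseInterval(start=5.5, width=2.0)
        assert iv.contains(5.6)
        assert iv.contains(0.5)
        assert not iv.contains(3.0)

    def test_matches_brute_force_phase_scan(self, second_model, second_stages):
        """Analytic interval vs 64-point simulation scan at the base point."""
        lin, thr, crit, kern = second_stages
        sig = ModulatingSignal(0.45, 0.05, SECOND_POINT.omega)
        iv = success_phase_interval(second_model, lin, thr, sig, 11.9,
                                    crit=crit, kernel=kern)
        phis, succ = phase_scan(second_model, sig, 11.9, n_phases=64,
                                config=default_response_config(second_model))
        assert int(np.sum(iv.contains(phis) == succ)) >= 62

    def test_continuity_of_interval_edges(self, second_model, second_stages):
        """P_S moves continuously from 0 to 1 as alpha crosses the band."""
        lin, thr, crit, kern = second_stages
        sig = ModulatingSignal(0.45, 0.05, SECOND_POINT.omega)
        alphas = thr.I_th + np.linspace(-3, 3, 41)
        ps = [prob_success(success_phase_interval(second_model, lin, thr, sig,
                                                  a, crit=crit, kernel=kern))
              for a in alphas]
        assert ps[0] == 0.0 and ps[-1] == 1.0
        assert np.all(np.diff(ps) >= 0)
        assert np.abs(np.diff(ps)).max() < 0.1


class TestThresholdVoltageSlope:
    def test_vth_vs_S0_is_nearly_affine(self, second_model):
        slope, _, r2, _ = vth_slope(second_model,
                                    [0.35, 0.40, 0.45, 0.50, 0.55, 0.60])
        assert r2 > 0.99
        assert slope > 0  # stronger inhibition raises the threshold voltage


class TestMonotonicity:
    def test_P_S_nonincreasing_in_S0(self, second_model):
        """More inhibition -> smaller success interval at fixed alpha."""
        from relaybounds import linearize
        ps = []
        for S0 in (0.40, 0.45, 0.50):
            lin = linearize(second_model, S0)
            thr = threshold_current(second_model, S0,
                                    config=default_response_config(second_model))
            iv = success_phase_interval(
                second_model, lin, thr,
                ModulatingSignal(S0, 0.05, SECOND_POINT.omega), 11.9)
            ps.append(prob_success(iv))
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))
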