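import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coreleasekit import (EventMeasurement, Sweep, dsi, event_kinetics,
                          gen_synaptic_trace, measure_events, nernst,
                          split_components, to_conductance, unitary_stats)
from coreleasekit.synaptic import ion_concentration

PIPETTE_K_GLUCONATE = {"K-gluconate": 130, "KCl": 5, "HEPES": 10, "MgCl2": 3,
                       "Na2ATP": 2, "NaGTP": 0.3, "EGTA": 0.6}
ACSF = {"NaCl": 130, "KCl": 3.5, "NaHCO3": 24, "NaH2PO4": 1.25,
        "MgCl2": 1.5, "CaCl2": 2.5, "glucose": 10}


class TestNernst:
    def test_salt_formula_parsing(self):
        assert ion_concentration({"KCl": 5}, "Cl") == 5
        assert ion_concentration({"MgCl2": 3}, "Cl") == 6
        assert ion_concentration({"K2HPO4": 2}, "K") == 4
        assert ion_concentration({"K-gluconate": 130}, "Cl") == 0
        assert ion_concentration(PIPETTE_K_GLUCONATE, "Cl") == 11
        assert ion_concentration(ACSF, "Cl") == 141.5

    def test_equal_concentrations_give_zero(self):
        assert nernst({"KCl": 10}, {"KCl": 10}, "Cl", -1) == pytest.approx(0.0)

    def test_chloride_reversal_of_recording_solutions(self):
        """5 KCl + 3 MgCl2 pipette vs standard aCSF gives E_Cl = -67 mV."""
        e = nernst(PIPETTE_K_GLUCONATE, ACSF, "Cl", -1, temperature=33.0)
        assert round(e) == -67

    def test_monovalent_cation_tenfold_gradient(self):
        """RT/F * ln(10) at 25 C is 59.2 mV."""
        e = nernst({"XCl": 10}, {"XCl": 100}, "X", 1, temperature=25.0)
        assert e == pytest.approx(59.2, abs=0.05)

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            nernst({"K-gluconate": 130}, ACSF, "Cl", -1)

    @given(st.floats(1.0, 200.0), st.floats(1.0, 200.0))
    def test_antisymmetry_and_monotonicity(self, c_in, c_out):
        e = nernst({"XCl": c_in}, {"XCl": c_out}, "Cl", -1, 33.0)
        rev = nernst({"XCl": c_out}, {"XCl": c_in}, "Cl", -1, 33.0)
        assert e == pytest.approx(-rev, abs=1e-9)
        assert math.copysign(1, e) == math.copysign(
            1, -math.log(c_out / c_in)) or abs(e) < 1e-9


class TestMeasureEvents:
    def test_flat_noiseless_trace_gives_failures(self):
        sw = Sweep(samples=np.zeros(20000), dt=5e-5, clamp_mode="voltage_clamp")
        events = measure_events(sw, [0.05, 0.07], window=15)
        assert all(e.is_failure and e.amplitude == 0.0 for e in events)

    def test_single_noiseless_psc_measured_exactly(self, cfg_noiseless):
        sweeps, truth = gen_synaptic_trace(cfg_noiseless, pulse_times=[0.05],
                                           g_gaba=2.5, v_hold=-40.0,
                                           e_gaba=-60.0)
        ev = measure_events(sweeps[0], [0.05], window=15)[0]
        assert ev.amplitude == pytest.approx(
            truth.per_sweep[0]["events"][0]["peak_pa"], rel=1e-3)
        assert ev.polarity == "outward"
        assert ev.latency == pytest.approx(1.0, abs=0.3)  # 10% onset point

    def test_failure_rate_recovered_within_binomial_ci(self, make_cfg):
        sweeps, _ = gen_synaptic_trace(make_cfg(seed=11, noise_sd=1.0),
                                       pulse_times=[0.05], g_gaba=2.0,
                                       v_hold=-40.0, e_gaba=-60.0,
                                       failure_p=0.3, n_sweeps=500)
        rate = np.mean([measure_events(sw, [0.05], trial=i)[0].is_failure
                        for i, sw in enumerate(sweeps)])
        ci = 2.576 * np.sqrt(0.3 * 0.7 / 500)
        assert abs(rate - 0.3) < ci + 0.02  # detection adds a little error

    def test_window_overlapping_next_pulse_rejected(self):
        sw = Sweep(samples=np.zeros(20000), dt=5e-5, clamp_mode="voltage_clamp")
        with pytest.raises(ValueError, match="overlap"):
            measure_events(sw, [0.05, 0.06], window=15)


def make_events(amps, trial0=0):
    return [EventMeasurement(trial=trial0 + i, pulse=0, amplitude=a,
                             is_failure=(a == 0.0))
            for i, a in enumerate(amps)]


class TestUnitaryStats:
    def test_hand_computed_cv(self):
        """{80, 100, 120} pA: mean 100, sample SD 20, CV 0.2."""
        s = unitary_stats(make_events([80.0, 100.0, 120.0]), min_trials=3)
        assert s.amplitude == pytest.approx(100.0)
        assert s.cv == pytest.approx(0.2, rel=1e-9)

    def test_identical_pulses_give_unity_ppr(self):
        first = make_events([-100.0] * 10)
        s = unitary_stats(first, second_events=make_events([-100.0] * 10))
        assert s.ppr == pytest.approx(1.0)

    def test_amplitude_potency_failure_identity(self):
        """amplitude = potency * (1 - failure rate), exactly by construction."""
        s = unitary_stats(make_events([-100.0, 0.0] * 5))
        assert s.amplitude == pytest.approx(-50.0)
        assert s.potency == pytest.approx(-100.0)
        assert s.amplitude == pytest.approx(
            s.potency * (1 - s.failure_rate), rel=1e-12)

    def test_all_failures_leave_potency_missing(self):
        s = unitary_stats(make_events([0.0] * 10))
        assert s.potency is None and s.cv is None
        assert s.failure_rate == 1.0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="trials"):
            unitary_stats(make_events([-50.0] * 5))

    def test_ppr_recovers_generated_depression(self, make_cfg):
        """With multiplicative depression f per preceding success and no
        failures, mean(second)/mean(first) approaches f."""
        f = 0.8
        sweeps, _ = gen_synaptic_trace(make_cfg(seed=21, noise_sd=0.5),
                                       pulse_times=[0.05, 0.07], g_gaba=2.0,
                                       v_hold=-40.0, e_gaba=-60.0,
                                       cv_q=0.2, depression_f=f, n_sweeps=60)
        first, second = [], []
        for i, sw in enumerate(sweeps):
            ev = measure_events(sw, [0.05, 0.07], trial=i)
            first.append(ev[0])
            second.append(ev[1])
        s = unitary_stats(first, second)
        assert s.ppr == pytest.approx(f, rel=0.12)


class TestEventKinetics:
    @staticmethod
    def psc(tau_rise=0.5, tau_decay=10.0, amp=-50.0, dt=5e-5):
        t = np.arange(int(0.2 / dt)) * dt
        tr, td = tau_rise * 1e-3, tau_decay * 1e-3
        shape = np.exp(-t / td) - np.exp(-t / tr)
        shape /= shape.max()
        return Sweep(samples=amp * shape, dt=dt, clamp_mode="voltage_clamp")

    def test_decay_tau_recovered_within_five_percent(self):
        _, tau = event_kinetics(self.psc(tau_decay=10.0))
        assert tau == pytest.approx(10.0, rel=0.05)

    def test_instant_rise_has_subsample_rise_time(self):
        sw = self.psc()
        sw.samples = np.concatenate([[0.0], sw.samples[:-1] * 0 - 50.0])
        sw.samples[0] = 0.0
        rise, _ = event_kinetics(sw)
        assert rise < 2 * sw.dt * 1e3

    def test_scale_invariance(self):
        r1, t1 = event_kinetics(self.psc(amp=-50.0))
        r2, t2 = event_kinetics(self.psc(amp=-100.0))
        assert r1 == pytest.approx(r2, rel=1e-9)
        assert t1 == pytest.approx(t2, rel=1e-9)


class TestConductance:
    def test_zero_peak_gives_zero(self):
        assert to_conductance(0.0, -40.0, -60.0) == 0.0

    def test_outward_gaba_conversion(self):
        assert to_conductance(200.0, -40.0, -60.0) == pytest.approx(10.0)

    def test_inward_glutamate_conversion(self):
        assert to_conductance(-100.0, -30.0, 0.0) == pytest.approx(10.0 / 3)

    def test_sign_mismatch_flagged(self):
        with pytest.raises(ValueError, match="mis-assigned"):
            to_conductance(-100.0, -40.0, -60.0)

    def test_small_driving_force_refused(self):
        with pytest.raises(ValueError, match="driving force"):
            to_conductance(50.0, -58.0, -60.0)

    def test_round_trip_with_generator(self, cfg_noiseless):
        """g * driving force -> peak -> g recovers the generated conductance."""
        sweeps, _ = gen_synaptic_trace(cfg_noiseless, pulse_times=[0.05],
                                       g_gaba=3.0, v_hold=-40.0, e_gaba=-60.0)
        g = to_conductance(sweeps[0].samples.max(), -40.0, -60.0)
        assert g == pytest.approx(3.0, rel=0.02)


class TestSplitComponents:
    def test_pure_gaba_leaves_glutamate_absent(self, make_cfg):
        sweeps, _ = gen_synaptic_trace(make_cfg(seed=4, noise_sd=0.5),
                                       pulse_times=[0.05], g_gaba=5.0,
                                       g_ampa=0.0, v_hold=-40.0, e_gaba=-60.0)
        g_gaba, g_glu, ratio = split_components(sweeps[0], -40.0, -60.0, 0.0)
        assert g_gaba.g == pytest.approx(5.0, rel=0.1)
        assert g_glu.g == 0.0 and ratio is None

    def test_mixed_trace_with_isolated_glutamate(self, cfg_noiseless):
        """GABA from the mixed trace, glutamate from a GABA-silenced trace
        (the pharmacological-isolation configuration): ratio 10 within 5%."""
        mixed, _ = gen_synaptic_trace(cfg_noiseless, pulse_times=[0.05],
                                      g_gaba=10.0, g_ampa=1.0, v_hold=-40.0,
                                      e_gaba=-60.0, e_ampa=0.0)
        iso, _ = gen_synaptic_trace(cfg_noiseless, pulse_times=[0.05],
                                    g_gaba=0.0, g_ampa=1.0, v_hold=-40.0,
                                    e_ampa=0.0)
        g_gaba, g_glu, ratio = split_components(
            mixed[0], -40.0, -60.0, 0.0, glu_isolated=iso[0])
        assert g_gaba.g == pytest.approx(10.0, rel=0.05)
        assert g_glu.g == pytest.approx(1.0, rel=0.05)
        assert ratio == pytest.approx(10.0, rel=0.05)

    def test_zero_gaba_driving_force_refused(self, cfg_noiseless):
        sweeps, _ = gen_synaptic_trace(cfg_noiseless, pulse_times=[0.05],
                                       g_gaba=1.0, v_hold=-40.0, e_gaba=-60.0)
        with pytest.raises(ValueError):
            split_components(sweeps[0], -60.0, -60.0, 0.0)


class TestDSI:
    def test_suppression_arithmetic(self):
        r = dsi(make_events([-200.0] * 5), make_events([-50.0] * 5))
        assert r.suppression == pytest.approx(75.0)

    def test_no_change_is_zero_suppression(self):
        r = dsi(make_events([-120.0] * 6), make_events([-120.0] * 6))
        assert r.suppression == pytest.approx(0.0)

    def test_complete_failure_is_full_suppression(self):
        r = dsi(make_events([-120.0] * 6), make_events([0.0] * 6))
        assert r.suppression == pytest.approx(100.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            dsi(make_events([0.0] * 6), make_events([0.0] * 6))

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            dsi(make_events([-100.0] * 3), make_events([-50.0] * 5))
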