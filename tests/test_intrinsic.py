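import numpy as np
import pytest

from coreleasekit import (StepProtocol, Sweep, SynthConfig, ap_features,
                          detect_spikes, gen_ap_train, gen_passive_steps,
                          input_resistance, resting_potential,
                          sag_fraction_for_index, sag_index, time_constant,
                          train_stats)
from coreleasekit.intrinsic import SpikeTrain, _adaptation_from_isis


def flat_sweep(v=-60.0, n=20000, dt=5e-5, stim_onset=0.2):
    stim = (StepProtocol(onset=stim_onset, duration=0.5, amplitude=-20.0)
            if stim_onset else None)
    return Sweep(samples=np.full(n, v), dt=dt, clamp_mode="current_clamp",
                 stim=stim)


class TestRestingPotential:
    def test_constant_trace(self):
        assert resting_potential(flat_sweep(-60.0)) == pytest.approx(-60.0)

    def test_noisy_baseline_recovers_mean(self, rng):
        sw = flat_sweep(-56.9)
        sw.samples += rng.normal(0, 0.3, sw.n_samples)
        n_base = int(0.2 / sw.dt)
        se = 0.3 / np.sqrt(n_base)
        assert resting_potential(sw) == pytest.approx(-56.9, abs=5 * se)

    def test_stimulus_at_time_zero_rejected(self):
        sw = Sweep(samples=np.full(20000, -60.0), dt=5e-5,
                   clamp_mode="current_clamp",
                   stim=StepProtocol(onset=0.0, duration=0.5, amplitude=-20))
        with pytest.raises(ValueError, match="baseline"):
            resting_potential(sw)


class TestInputResistance:
    def test_noiseless_family_is_exact(self, cfg_noiseless):
        sweeps, _ = gen_passive_steps(cfg_noiseless, rm=100.0, cm=150.0)
        assert input_resistance(sweeps) == pytest.approx(100.0, rel=1e-6)

    def test_large_deflections_excluded_without_changing_slope(self, make_cfg):
        cfg = make_cfg(seed=2, noise_sd=0.3)
        small = [-20, -15, -10, -5, 5, 10, 15, 20]
        sweeps, _ = gen_passive_steps(cfg, rm=158.5, cm=131.2,
                                      step_amplitudes=small)
        # +250 pA deflects ~+40 mV: must be excluded, slope unchanged
        with_big, _ = gen_passive_steps(cfg, rm=158.5, cm=131.2,
                                        step_amplitudes=small + [250])
        assert input_resistance(with_big) == pytest.approx(
            input_resistance(sweeps), rel=1e-9)

    def test_invariant_under_step_reordering(self, make_cfg):
        sweeps, _ = gen_passive_steps(make_cfg(seed=3, noise_sd=0.3),
                                      rm=120.0, cm=150.0)
        assert input_resistance(sweeps[::-1]) == pytest.approx(
            input_resistance(sweeps), rel=1e-12)

    def test_too_few_qualifying_steps_reported(self, cfg_noiseless):
        sweeps, _ = gen_passive_steps(cfg_noiseless, rm=200.0, cm=100.0,
                                      step_amplitudes=[-200, -150, 150])
        with pytest.raises(ValueError, match="excluded"):
            input_resistance(sweeps)


class TestTimeConstant:
    def test_noiseless_exponential_recovered(self, cfg_noiseless):
        sweeps, _ = gen_passive_steps(cfg_noiseless, rm=100.0, cm=200.0,
                                      step_amplitudes=[-20.0] * 3,
                                      step_duration=0.4)
        tau, _ = time_constant(sweeps)
        assert tau == pytest.approx(20.0, rel=1e-4)

    def test_capacitance_from_tau_over_rm(self, cfg_noiseless, ref_cell):
        cm_true = ref_cell["tau_m"] * 1e3 / ref_cell["rm"]  # 131.2 pF
        sweeps, _ = gen_passive_steps(cfg_noiseless, rm=ref_cell["rm"],
                                      cm=cm_true,
                                      step_amplitudes=[-20.0] * 3,
                                      step_duration=0.4)
        tau, cm = time_constant(sweeps, r_m=ref_cell["rm"])
        assert cm == pytest.approx(131.2, abs=0.1)

    def test_mismatched_repeats_rejected(self, cfg_noiseless):
        a, _ = gen_passive_steps(cfg_noiseless, rm=100, cm=100,
                                 step_amplitudes=[-20], step_duration=0.4)
        b, _ = gen_passive_steps(cfg_noiseless, rm=100, cm=100,
                                 step_amplitudes=[-20], step_duration=0.3)
        with pytest.raises(ValueError, match="timing"):
            time_constant(a + b)


class TestSagIndex:
    @staticmethod
    def family(cfg, sag_frac, v_rest=-57.0, rm=158.5):
        amps = [a * 1e3 / rm for a in (-14, -18, -22, -26, -30, -34)]
        sag = ({"g_fraction": sag_frac, "tau_sag": 120.0}
               if sag_frac else None)
        return gen_passive_steps(cfg, rm=rm, cm=131.2, v_rest=v_rest,
                                 step_amplitudes=amps, step_duration=2.0,
                                 sag=sag)

    def test_passive_cell_has_index_one(self, cfg_noiseless):
        sweeps, _ = self.family(cfg_noiseless, None)
        assert sag_index(sweeps, -57.0) == pytest.approx(1.0, abs=1e-3)

    def test_formula_arithmetic(self):
        """V_rest -60, V_hyp -85, V_sag -80 gives (−60+80)/(−60+85) = 0.8."""
        assert (-60 + 80) / (-60 + 85) == pytest.approx(0.8)

    def test_recovers_generated_index(self, make_cfg):
        s = sag_fraction_for_index(0.83, 20.8, 120.0, 2.0)
        sweeps, truth = self.family(make_cfg(seed=3, noise_sd=0.2), s)
        est = sag_index(sweeps, -57.0)
        assert est == pytest.approx(truth.params["sag_index"], abs=0.02)

    def test_refuses_extrapolation(self, cfg_noiseless):
        # shallow family: V_sag never reaches -80 mV
        sweeps, _ = gen_passive_steps(
            cfg_noiseless, rm=158.5, cm=131.2, v_rest=-57.0,
            step_amplitudes=[-10, -20, -30, -40], step_duration=2.0)
        with pytest.raises(ValueError, match="extrapolat|range"):
            sag_index(sweeps, -57.0)


class TestDetectSpikes:
    def test_constant_trace_empty(self):
        assert detect_spikes(flat_sweep()).n_spikes == 0

    def test_subcriterion_ramp_empty(self):
        """A 5 mV/ms ramp never crosses the 10 mV/ms criterion."""
        dt = 5e-5
        v = -60 + 5.0 * np.arange(4000) * dt * 1e3
        sw = Sweep(samples=v, dt=dt, clamp_mode="current_clamp")
        assert detect_spikes(sw).n_spikes == 0

    def test_all_generated_spikes_found_at_their_peaks(self, cfg_noiseless):
        sweep, truth = gen_ap_train(cfg_noiseless, isis=[30.0] * 9,
                                    duration=0.4)
        train = detect_spikes(sweep)
        assert train.n_spikes == 10
        err = np.abs(train.spike_times - np.array(truth.params["peak_times_s"]))
        assert err.max() <= sweep.dt + 1e-12

    def test_count_symmetric_under_time_reversal(self, cfg_noiseless):
        sweep, _ = gen_ap_train(cfg_noiseless, isis=[30.0] * 9, duration=0.4)
        rev = Sweep(samples=sweep.samples[::-1].copy(), dt=sweep.dt,
                    clamp_mode="current_clamp")
        fwd = Sweep(samples=sweep.samples.copy(), dt=sweep.dt,
                    clamp_mode="current_clamp")
        assert detect_spikes(rev).n_spikes == detect_spikes(fwd).n_spikes

    def test_coarse_sampling_rejected(self):
        sw = Sweep(samples=np.zeros(100), dt=5e-4, clamp_mode="current_clamp")
        with pytest.raises(ValueError, match="dt"):
            detect_spikes(sw)


class TestAPFeatures:
    def test_triangular_spike_half_width(self):
        """1 ms linear rise + 2 ms linear fall, 60 mV tall: the half-level is
        crossed at 0.5 ms on the rise and 2.0 ms, so width is 1.5 ms."""
        dt = 5e-5
        base = np.full(4000, -60.0)
        rise = np.linspace(-60, 0, int(1e-3 / dt), endpoint=False)
        fall = np.linspace(0, -60, int(2e-3 / dt), endpoint=False)
        v = np.concatenate([base, rise, fall, np.full(4000, -60.0)])
        sw = Sweep(samples=v, dt=dt, clamp_mode="current_clamp")
        train = detect_spikes(sw)
        assert train.n_spikes == 1
        f = ap_features(sw, train.spike_times[0])
        assert f.half_width == pytest.approx(1.5, abs=0.08)

    @pytest.mark.parametrize("thr,amp,hw,ahp", [
        (-41.9, 57.4, 0.74, 10.3),
        (-39.9, 55.7, 0.80, 11.8),
        (-45.0, 70.0, 1.00, 8.0),
    ])
    def test_noiseless_parameter_recovery(self, cfg_noiseless, thr, amp,
                                          hw, ahp):
        sweep, _ = gen_ap_train(cfg_noiseless, threshold=thr, amplitude=amp,
                                half_width=hw, ahp=ahp, isis=[40.0] * 5,
                                duration=0.5)
        train = detect_spikes(sweep)
        f = ap_features(sweep, train.spike_times[0],
                        next_spike_time=train.spike_times[1])
        assert f.threshold == pytest.approx(thr, abs=0.1)
        assert f.amplitude == pytest.approx(amp, abs=0.1)
        assert f.half_width == pytest.approx(hw, abs=cfg_noiseless.dt * 1e3)
        assert f.ahp == pytest.approx(ahp, abs=0.1)
        assert f.max_rise > 10 and f.max_decay < 0

    def test_truncated_ahp_marked_missing(self, cfg_noiseless):
        sweep, _ = gen_ap_train(cfg_noiseless, isis=[40.0] * 3, duration=0.3,
                                tail=0.1)
        train = detect_spikes(sweep)
        # cut mid-repolarization: half-crossing passed, trough never reached
        cut = int((train.spike_times[0] + 1.0e-3) / sweep.dt)
        short = Sweep(samples=sweep.samples[:cut].copy(), dt=sweep.dt,
                      clamp_mode="current_clamp")
        f = ap_features(short, train.spike_times[0])
        assert f.ahp is None


class TestTrainStats:
    def test_regular_train_ratio_one(self):
        train = SpikeTrain(spike_times=0.1 + np.arange(10) * 0.025,
                           isis=np.full(9, 25.0), window=(0.1, 0.9))
        freq, ratio = train_stats(train)
        assert ratio == pytest.approx(1.0)
        assert freq == pytest.approx(10 / 0.8)

    def test_hand_computed_ratio(self):
        """ISIs 10,20,30,40,40,40 ms: mean(40,40,40)/10 = 4."""
        assert _adaptation_from_isis([10, 20, 30, 40, 40, 40]) == pytest.approx(4.0)

    def test_short_trains_use_last_two_isis(self):
        assert _adaptation_from_isis([10, 20, 30]) == pytest.approx(2.5)
        assert _adaptation_from_isis([10.0]) is None

    def test_generated_accommodating_train_recovered_exactly(self, cfg_noiseless):
        isis = [50.0, 45.0, 40.0, 35.0, 30.0, 25.0, 21.5, 21.5, 21.5]
        sweep, truth = gen_ap_train(cfg_noiseless, isis=isis, duration=0.8)
        freq, ratio = train_stats(detect_spikes(sweep))
        assert truth.params["adaptation_ratio"] == pytest.approx(0.43)
        assert ratio == pytest.approx(0.43, abs=0.005)
        assert freq == pytest.approx(truth.params["firing_frequency_hz"])
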