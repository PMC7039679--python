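# coreleasekit

Quantification toolkit for slice electrophysiology of synaptic corelease:
patch-clamp sweep analysis (intrinsic membrane and action-potential
properties), unitary postsynaptic-current statistics, GABA/glutamate
conductance dissociation, FFT-deconvolution release-rate estimation with
synchronicity ratios, depolarization-induced suppression of inhibition
(DSI), and gamma-band LFP power summaries — together with seeded
synthetic-trace generators that carry exact ground truth for every analysis
stage.

It is written for cellular electrophysiologists who want the full
measurement chain of a paired-recording / optogenetics study as tested,
scriptable code: every estimator is exercised against generators whose
parameters are the quantity the estimator is supposed to recover.

## What it computes

**Intrinsic properties** (current-clamp step families and spike trains):

- input resistance `R_m` by OLS regression of steady-state voltage
  deflections (±15 mV of rest, last 200 ms of 2 s steps) on injected
  current;
- membrane time constant `τ_m` by single-exponential fit
  `V(t) = V₀ + ΔV·(1 − e^(−t/τ))` to the average of twenty −20 pA / 400 ms
  pulses, and `C_m = τ_m / R_m`;
- sag index `(V_rest − V_sag)/(V_rest − V_hyp)` interpolated via polynomial
  V–I fits to the current at which `V_sag = −80 mV` (a measure of the
  hyperpolarization-activated cation current I_h);
- spike threshold at the upward crossing of `dV/dt = 10 mV/ms`, amplitude,
  half-width at half-amplitude (sub-sample interpolation), maximal
  rise/decay slopes, AHP depth, firing frequency, and the adaptation ratio
  (mean of the last interspike intervals over the first).

**Synaptic transmission** (voltage-clamp):

- per-trial evoked-event measurement with failure classification, latency
  (pulse to 10 %-of-peak onset) and onset polarity;
- amplitude (mean including failures), potency (mean excluding failures),
  failure rate, CV (sample SD / mean), paired-pulse ratio, 20–80 % rise
  time and single-exponential decay τ;
- Nernst reversal potentials from pipette/bath recipes,
  `E = (RT/zF)·ln([out]/[in])`, and conductance conversion
  `G = I_peak/(V_hold − E_rev)`;
- polarity-based dissociation of GABA_A (outward above E_Cl) and AMPA
  (inward, E_rev ≈ 0 mV) components, and DSI suppression
  `100·(1 − I_DSI/I_ctl)`.

**Release-rate deconvolution** (50 Hz, 25-pulse trains): the train response
is deconvolved by an artificial miniature IPSC (bi-exponential kernel scaled
to a 20 pA peak) in the frequency domain after 50 passes of 3-point binomial
smoothing. Per pulse, synchronous release is the release-rate area in the
5 ms bin after the pulse and asynchronous release the area in the 15 ms bin
before the next pulse; their ratio is the synchronicity ratio (SR).

**LFP spectra**: Welch periodograms (1 s Hann segments, 50 % overlap) of
10 s epochs summarized as peak frequency, peak power and integrated
20–80 Hz gamma power, plus before/during/after illumination modulation
ratios.

## Worked example

Recover a cell's membrane parameters from synthetic sweeps generated with
known truth (R_m = 158.5 MΩ, τ_m = 20.8 ms, sag index 0.83):

```python
from coreleasekit import (SynthConfig, gen_passive_steps, input_resistance,
                          time_constant, sag_fraction_for_index, sag_index)

cfg = SynthConfig(seed=1, noise_sd=0.3)          # 20 kHz, 0.3 mV noise
steps, _ = gen_passive_steps(cfg, rm=158.5, cm=131.2, v_rest=-56.9,
                             step_amplitudes=[-20, -15, -10, -5, 5, 10, 15, 20])
print(f"R_m  = {input_resistance(steps):.1f} MOhm")

pulses, _ = gen_passive_steps(cfg, rm=158.5, cm=131.2, v_rest=-56.9,
                              step_amplitudes=[-20.0] * 20, step_duration=0.4)
tau, cm = time_constant(pulses, r_m=158.5)
print(f"tau_m = {tau:.2f} ms, C_m = {cm:.1f} pF")

frac = sag_fraction_for_index(0.83, 20.8, 120.0, 2.0)
deep, _ = gen_passive_steps(SynthConfig(seed=3, noise_sd=0.2), rm=158.5,
                            cm=131.2, v_rest=-56.9, step_duration=2.0,
                            step_amplitudes=[-88, -114, -139, -164, -189, -215],
                            sag={"g_fraction": frac, "tau_sag": 120.0})
print(f"sag index = {sag_index(deep, -56.9):.3f}")
```

prints

```
R_m  = 158.6 MOhm
tau_m = 20.65 ms, C_m = 130.3 pF
sag index = 0.828
```

— the regression recovers the planted input resistance within 0.1 MΩ, the
exponential fit the time constant within 0.8 %, and the sag interpolation
the planted index within 0.002 despite the added noise.

A full simulate→analyze→report run (deterministic for a fixed seed):

```sh
coreleasekit run --out run_out           # all stages, default config
coreleasekit simulate --preset train --seed 5 --out sim
coreleasekit deconv --in sim/sweeps.native --rise 0.8 --decay 9 --out sr.csv
```

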