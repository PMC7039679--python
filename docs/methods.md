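# Methods

This note documents the models, estimators and numerical choices behind
coreleasekit, what the synthetic generators do and do not emulate, and the
known limitations.

## Data model and units

A `Sweep` is one uniformly sampled trace with a sampling interval `dt`
(seconds), a clamp mode that fixes the sample units (current clamp and
field: mV; voltage clamp: pA), a holding level, and optional stimulus
metadata (step onset/duration/amplitude and presynaptic pulse times). Time
is seconds everywhere inside the package; kinetic quantities exposed to
users (rise times, decay constants, half-widths, latencies) are
milliseconds at function boundaries only. Inward currents are negative,
outward positive; conductances are always reported positive with a
component label.

The native interchange format is plain text: a file header (`key: value`,
with solutions and free-form metadata as JSON) followed by one block per
sweep, each a small header plus one column of samples written with 17
significant digits. Round-tripping is exactly lossless for float64, and a
read-back recording rewrites to a byte-identical file. Sweeps are stored as
sequential blocks rather than side-by-side columns so that sweeps of
different length or `dt` coexist in one file. ABF import is delegated to
`pyabf` when installed; only the mapping onto `Sweep` is owned here.

## Synthetic generators

Every generator is driven by a `SynthConfig(seed, dt, noise_sd)`. Each call
derives one RNG stream per sweep from `(seed, generator tag, sweep index)`,
so identical configs are bit-identical and generating more sweeps never
perturbs earlier ones. Noise is additive white Gaussian; default `dt` is
50 µs (20 kHz digitization, the standard slice-rig rate).

**Passive steps.** The membrane is a single RC compartment:
`V(t) = V_rest + I·R_m·(1 − e^(−t/τ))f_sag(t)` with `τ = R_m·C_m`. Sag — the
relaxation produced by the hyperpolarization-activated cation current I_h —
is modelled phenomenologically as a multiplicative relaxation
`f_sag(t) = 1 − s·(1 − e^(−t/τ_sag))` toward a steady state reduced by the
fraction `s`. Because the model is linear in the injected current, the
noiseless sag index (steady-state over peak deflection) is
amplitude-independent, and `sag_fraction_for_index` solves for `s` giving
any requested index by bracketing, so the generator truth is exact. Default
`τ_sag` is 120 ms, a typical I_h activation time constant at ~33 °C. What
is *not* emulated: the voltage dependence of I_h (sag in real cells grows
with hyperpolarization depth), electrode artifacts, and slow drift.

**Action-potential trains.** Spikes are parametric waveforms, not a
conductance model: the analyses measure waveform geometry only, so the
geometry must be exactly controllable. Each spike is piecewise polynomial —
a cubic foot leaving the depolarized plateau, a window of ±0.15 ms around
the threshold crossing in which the voltage is exactly quadratic in time
(dV/dt linear, passing through 10 mV/ms precisely at the threshold
parameter), a cubic Hermite upstroke to the peak (threshold + amplitude), a
cubic repolarization to the trough (threshold − AHP), and a slow cubic
recovery to the plateau. The quadratic window matters numerically: the
analyzer's central-difference slope and linear interpolation are exact for
a parabola, so threshold recovery on noiseless traces is limited only by
round-off (~0.02 mV at 20 kHz), not discretization. The upstroke duration
is solved (bracketing on a monotone map) so the waveform's half-amplitude
width equals the `half_width` parameter; the repolarization lasts twice the
rise, which puts the maximal rise/decay slopes near 170/−100 mV/ms for
typical parameters, in the physiological range for interneurons. Spikes are
placed at cumulative inter-spike intervals on the plateau; overlapping
waveforms raise an error rather than distorting silently.

**Synaptic traces.** Per presynaptic pulse and per component (GABA_A:
default 0.8 ms rise / 9 ms decay, E_rev configurable, typically −60 mV
under the low-chloride configuration or ~0 mV with high internal chloride;
AMPA: 0.2/2 ms, E_rev ≈ 0 mV) the generator draws: a Bernoulli failure; a
lognormal quantal scale with mean 1 and configurable CV; multiplicative
short-term depression (amplitude × f per preceding success of the same
component); and a release time — synchronous (fixed latency, default 1 ms,
plus Gaussian jitter of SD 0.2 ms) or, with a per-pulse probability,
asynchronous, uniform within a window (default 15 ms) ending at the next
pulse onset. The asynchronous fraction rising linearly across a train
reproduces the progressive desynchronization phenotype of CCK-type
GABAergic transmission. Currents are `Σ g_i(t)·(V_hold − E_i)` with
unit-peak bi-exponential conductance shapes; nS × mV = pA. The latency
jitter and quantal CV are conventional placeholder values (no measured
values exist for these cells) and are flagged as placeholders in the
ground-truth sidecar the CLI writes. Not emulated: receptor saturation and
desensitization, series-resistance filtering, vesicle-pool depletion
dynamics beyond the geometric depression law, and tonic currents.

**LFP.** A sinusoid at `f0` plus white noise. This is sufficient for
validating spectral summaries (peak location, band power, Parseval) but
carries none of the nonstationarity, 1/f background or harmonic structure
of carbachol-induced oscillations; passing spectral tests demonstrates
correctness of the spectral estimator, not realism of the rhythm.

Because the generators' ground truth is sufficient to predict every
analysis output without re-simulation, parameter-recovery tests plant the
reference basket-cell means (R_m 158.5 MΩ, τ_m 20.8 ms, sag index 0.83,
threshold −41.9 mV, amplitude 57.4 mV, half-width 0.74 ms, AHP 10.3 mV,
adaptation ratio 0.43) as truth and require the estimators to return them.

## Intrinsic-property estimators

- **Resting potential**: mean of ≥100 ms of pre-stimulus baseline. (The
  cell-attached ramp method used experimentally is an acquisition
  technique, not an analysis, and is out of scope.)
- **Input resistance**: OLS slope (with intercept) of steady-state
  deflection — mean over the last 200 ms of the step, minus the sweep's own
  baseline — against injected current; steps deflecting more than 15 mV
  from rest are excluded before fitting and at least three qualifying steps
  are required. mV/pA = GΩ. The estimate is invariant under step reordering
  and under adding excluded steps.
- **Time constant**: repeats of the −20 pA / 400 ms pulse are averaged
  (identical timing enforced), then `V₀ + ΔV(1 − e^(−t/τ))` is fit by
  Levenberg–Marquardt from pulse onset over five initial-guess time
  constants (guess: time to 63.2 % of the steady-state deflection). Fits
  outside 0.5–200 ms are rejected as errors rather than returned.
  Capacitance is derived as `C_m = τ_m/R_m` — a definition, not an
  independent measurement.
- **Sag index**: per hyperpolarizing step, `V_hyp` is the minimum of a 2 ms
  boxcar-smoothed copy of the step segment and `V_sag` the raw mean over
  the last 200 ms. Smoothing for `V_hyp` is deliberate: the raw
  sample-minimum over a 2 s step at 20 kHz sits ~4.6 noise SDs below the
  true trough (an extreme-value bias), which would systematically depress
  the index; the trough itself is a ~20 ms event, so 2 ms smoothing is
  conservative. Cubic polynomials (quadratic when fewer than five steps)
  are fit to both V–I relations, the current `I*` with `V_sag(I*) = −80 mV`
  is solved for within the sampled range — extrapolation is refused — and
  the index is evaluated at `I*`.
- **Spike detection**: dV/dt by central differences on the raw, unfiltered
  trace; an onset is an upward crossing of 10 mV/ms (located by linear
  interpolation) followed within 2 ms by a local maximum at least 20 mV
  above the onset voltage; spikes are stamped at the peak, with a 1 ms
  refractory exclusion. An empty train is a valid result.
- **AP features**: threshold is the interpolated voltage at the crossing;
  amplitude is peak − threshold; half-width is the interpolated interval
  between the two crossings of threshold + amplitude/2; maximal slopes are
  the dV/dt extrema between onset and trough; AHP is threshold minus the
  trough minimum searched ≤20 ms after the peak or until the next spike.
  AHP is reported as a positive depth (threshold − trough), per its
  defining formula. If the sweep ends before the trough, AHP is missing
  rather than wrong.
- **Adaptation ratio**: mean of the last three ISIs over the first when at
  least five ISIs exist, last two for 2–4 ISIs, undefined below that — a
  deterministic reading of the "last 2–3 intervals" convention. Firing
  frequency is spike count over the stimulus duration.

## Synaptic estimators

- **Event measurement**: per pulse, the signed extremum within the response
  window (default 15 ms, must not overlap the next pulse), referenced to a
  *local* baseline — the mean of the 2 ms before that pulse. Local
  referencing matters in 50 Hz trains: with ~9 ms decays, later responses
  ride on the preceding tail, and a global baseline inflates paired-pulse
  ratios by ~15–20 %. Latency is the pulse-to-onset interval, onset being
  the first crossing of 10 % of the peak.
- **Failure criterion**: decided on a 0.5 ms boxcar-smoothed copy against
  `k·σ_s·sqrt(2·ln 2m)` with k = 3 (configurable), σ_s the smoothed
  baseline SD and m the number of effectively independent smoothed samples
  in the window. The extreme-value factor is essential: the expected
  maximum of pure noise over a multi-millisecond window is itself ~3.3 SD,
  so a plain 3-SD bar misclassifies most true failures at any noise level.
  With the corrected statistic, generated failure rates are recovered
  within binomial sampling error. Failures are recorded with amplitude
  0 pA, which makes amplitude = potency × (1 − failure rate) an exact
  identity.
- **Unitary statistics**: amplitude is the mean over all trials including
  failures; potency excludes them; CV is the sample (n−1) SD of all trial
  amplitudes over the mean (failure trials included — the variance of
  transmission includes failures); PPR is mean second-pulse over mean
  first-pulse amplitude. Ten consecutive trials minimum.
- **Kinetics**: 20–80 % rise time with sub-sample interpolation; decay τ by
  single-exponential least squares from the peak down to 5 % of it.
- **Nernst / conductance**: solution recipes are maps from salt formula to
  mM; the ion count per salt is parsed from the formula (Cl in MgCl₂
  counts twice; organic anions contribute nothing). `E = (RT/zF)·ln(out/in)`
  at the bath temperature; `G = I_peak/(V_hold − E_rev)` with a minimum
  5 mV driving force, and a current whose sign contradicts the driving
  force is an error (a mis-assigned component), not a negative conductance.
- **Polarity dissociation**: with E_Cl below the holding potential, GABA_A
  responses are outward and AMPA responses inward, so the two conductances
  are read from the outward and inward extrema. When a pharmacologically
  isolated glutamate trace is available, the glutamate conductance is
  measured there and the GABA conductance on (mixed − isolated): the fast
  inward AMPA transient otherwise truncates the slower outward GABA peak by
  ~6–9 % even with typical kinetics. Component presence uses the same
  extreme-value-corrected threshold as event detection.
- **DSI**: condition averages of ≥5 events; suppression
  `100·(1 − Ī_DSI/Ī_ctl)` %.

## Deconvolution

The train current is modelled as release rate ⊛ miniature-PSC kernel. The
kernel is a bi-exponential difference built from the unitary response's
rise/decay kinetics, scaled so its discrete peak is exactly 20 pA, and at
least five decay constants long. The trace is baseline-subtracted, smoothed
by 50 passes of the (¼, ½, ¼) binomial kernel with edge replication
(equivalent to a Gaussian of SD 5 samples = 0.25 ms at 20 kHz), sign-
matched to the kernel (inward trains are flipped), and divided by the
kernel spectrum point-by-point after zero-padding both to a power of two at
least the sum of their lengths (preventing circular wraparound).
Regularization: kernel-spectrum magnitudes below `ε = 10⁻³` of the spectral
maximum are clamped to that floor with phase preserved — discretized
kernels have near-zero high-frequency magnitudes that would otherwise
amplify noise unboundedly; `ε → 0` recovers raw division. The DC bin is
never floored, so total quantal count is conserved exactly
(rate area = trace charge / kernel charge).

Rates are quanta/s: one quantum is one kernel's worth of charge, and
deconvolving the kernel itself yields a unit-area impulse. Per pulse,
synchronous release is the rate area over [onset, onset + 5 ms] and
asynchronous release the area over the 15 ms before the next onset; the
final pulse uses a virtual next onset one period later. SR = sync/async,
flagged undefined (NaN) when the asynchronous area is below 10⁻³ quanta
rather than reported as a spurious large number. Deconvolution is per
sweep, with per-pulse areas averaged across sweeps before forming SRs.

## Spectra

Welch periodograms: 1 s Hann segments, 50 % overlap, per-segment linear
detrend, density scaling (these settings are recorded in the output
metadata and configurable). Peak frequency/power are searched in 10–100 Hz;
gamma-band power integrates the density over the inclusive 20–80 Hz band.
Both the density at the peak and the integrated band power are reported.
Total spectral power matches the time-domain variance within 2 % for
stationary signals. Illumination modulation reports during/pre and post/pre
ratios of peak and band power plus the peak-frequency shift; a during/pre
band ratio below 0.1 is flagged suppressed (the residual then reflects the
noise floor, not the oscillation).

## Pipeline and determinism

`RunConfig` merges user overrides into a complete default tree (unknown
keys are rejected by name, nested included) whose numeric defaults mirror
the acquisition protocol: 20 kHz sampling, 2 s step families with 5 pA
granularity, twenty −20 pA/400 ms pulses, 25-pulse 50 Hz trains, 5/15 ms
synchronicity bins, 20–80 Hz gamma band. Stage seeds are derived from the
single run seed; outputs are CSV/JSON written with fixed float formatting
and sorted keys, so identical configs produce byte-identical files. The
manifest records package version, config hash, seed and file list — enough
to reproduce any table. Default problem sizes (e.g. 10 train sweeps, 20
unitary trials, 10 s LFP epochs) run the full pipeline in about a second;
they are chosen as the smallest sizes at which the recovery tolerances
above hold comfortably.

## Limitations

- The generators validate estimator correctness, not biological realism:
  passing recovery tests says the estimators are unbiased under the stated
  noise model, not that they are robust to electrode drift, series
  resistance, or non-Gaussian noise in real recordings.
- Sag is amplitude-independent in the generator but voltage-dependent in
  real neurons; the −80 mV interpolation convention is what makes the real
  measurement comparable across cells, and only that convention is tested.
- Capacitance is τ/R by definition here; estimators based on charge
  integration would differ on real cells with dendritic filtering.
- The deconvolution assumes a stationary quantal waveform; amplitude
  scaling (depression) is absorbed into the rate, which is the intended
  interpretation, but kinetic changes during a train would bias it.
- Automatic rheobase search is not implemented; the rheobase sweep is
  identified by stimulus metadata.
- No spontaneous-event (template-matching) detection, no Bayesian or
  non-negative deconvolution, no time–frequency analysis.
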