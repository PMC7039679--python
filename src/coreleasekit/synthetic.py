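"""Seeded synthetic-sweep generators with exact ground truth.

Every generator emulates one stage of the slice-physiology protocol the
analysis modules quantify:

* :func:`gen_passive_steps` — 2 s current-step families (RC charging, with an
  optional slow sag relaxation emulating the hyperpolarization-activated
  cation current I_h);
* :func:`gen_ap_train` — 800 ms accommodating spike trains built from
  parametric action-potential waveforms whose measurable geometry (threshold
  at the 10 mV/ms point, peak, half-width, AHP trough) equals the requested
  parameters exactly;
* :func:`gen_synaptic_trace` — 20 kHz voltage-clamp traces of mixed GABA_A
  (slow, E_rev near -60 mV) and AMPA (fast, E_rev near 0 mV) postsynaptic
  currents with quantal variability, failures, paired-pulse depression and
  progressively asynchronous release during 50 Hz trains;
* :func:`gen_lfp` — carbachol-style gamma-band field oscillations.

Randomness is fully determined by ``SynthConfig.seed``: each generator call
derives one independent RNG stream per sweep from ``(seed, stream tag,
sweep index)``, so adding sweeps never perturbs earlier ones and identical
configs are bit-identical.

The action-potential waveform is piecewise polynomial. A key numerical
choice: in a +/-0.15 ms window around the threshold crossing the voltage is
exactly quadratic in time (dV/dt linear through 10 mV/ms), which makes the
analyzer's central-difference slope and linear interpolation exact there —
threshold recovery on noiseless traces is then limited only by float
round-off, not by discretization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .trace_io import Sweep, StepProtocol

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "gen_passive_steps",
    "gen_ap_train",
    "gen_synaptic_trace",
    "gen_lfp",
    "gen_dsi_epochs",
    "sag_fraction_for_index",
]

# stream tags keep RNG streams of different generators disjoint
_TAG_PASSIVE, _TAG_AP, _TAG_SYN, _TAG_LFP = 11, 12, 13, 14


@dataclass(frozen=True)
class SynthConfig:
    """Seed and trace-level parameters shared by all generators.

    noise_sd is the SD of additive white Gaussian noise, in the units of the
    generated trace (mV for current clamp / field, pA for voltage clamp).
    """

    seed: int = 0
    dt: float = 5e-5
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self, tag: int, index: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, tag, index])


@dataclass
class GroundTruth:
    """Generator parameters actually used, sufficient to predict analyses.

    ``params`` holds scalar truths (e.g. rm_mohm, sag_index, threshold_mv);
    ``per_sweep`` holds one record per emitted sweep (per-step deflections,
    per-event release times / amplitudes / failure flags, ...).
    """

    params: dict = field(default_factory=dict)
    per_sweep: list = field(default_factory=list)


def _noise(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if cfg.noise_sd == 0:
        return np.zeros(n)
    return rng.normal(0.0, cfg.noise_sd, n)


# ---------------------------------------------------------------------------
# passive steps / sag


def _passive_shape(t: np.ndarray, tau_m_s: float, sag_fraction: float,
                   tau_sag_s: float) -> np.ndarray:
    """Normalized step response: RC charging times a slow sag relaxation.

    Returns f(t) with the steady-state (no-sag) deflection normalized to 1;
    with sag the late response relaxes toward ``1 - sag_fraction``.
    """
    f = 1.0 - np.exp(-t / tau_m_s)
    if sag_fraction:
        f = f * (1.0 - sag_fraction * (1.0 - np.exp(-t / tau_sag_s)))
    return f


def sag_fraction_for_index(target_index: float, tau_m_ms: float,
                           tau_sag_ms: float, step_duration_s: float,
                           ss_window_s: float = 0.2) -> float:
    """Solve for the sag relaxation fraction giving a desired sag index.

    The sag index of the noiseless generator waveform — steady-state
    deflection (mean over the last ``ss_window_s``) divided by the peak
    deflection — is amplitude-independent, so one fraction fixes the truth
    for a whole step family.
    """
    if not (0 < target_index < 1):
        raise ValueError("target sag index must lie in (0, 1)")
    t = np.arange(0.0, step_duration_s, 1e-5)
    n_ss = int(round(ss_window_s / 1e-5))

    def index_of(s):
        f = _passive_shape(t, tau_m_ms / 1e3, s, tau_sag_ms / 1e3)
        return f[-n_ss:].mean() / f.max()

    return brentq(lambda s: index_of(s) - target_index, 1e-6, 0.95, xtol=1e-10)


def gen_passive_steps(cfg: SynthConfig, *, rm: float, cm: float,
                      v_rest: float = -60.0,
                      step_amplitudes: Sequence[float] = (-20, -15, -10, -5, 5, 10, 15, 20),
                      step_duration: float = 2.0,
                      onset: float = 0.2, tail: float = 0.3,
                      sag: Optional[dict] = None):
    """Current-clamp step family from an RC cell, optionally with sag.

    Parameters
    ----------
    rm : float
        Input resistance, MΩ.
    cm : float
        Capacitance, pF (membrane time constant tau = rm*cm).
    step_amplitudes : sequence of float
        Injected currents in pA, one sweep each (repeats allowed — e.g. 20
        repeats of -20 pA for time-constant estimation).
    step_duration : float
        Step length in seconds (the protocol uses 2 s steps; tau pulses 0.4 s).
    sag : dict, optional
        ``{"g_fraction": s, "tau_sag": ms}`` — late relaxation of the
        deflection by fraction ``s`` with time constant ``tau_sag``.

    Returns
    -------
    (list of Sweep, GroundTruth)
        Ground truth records rm, cm, tau_m, the sag index of the noiseless
        waveform, and per-step noiseless V_hyp / V_sag.
    """
    if rm <= 0 or cm <= 0:
        raise ValueError("rm and cm must be positive")
    tau_s = rm * 1e6 * cm * 1e-12  # MΩ * pF -> s
    sag_fraction = 0.0
    tau_sag_ms = 100.0
    if sag is not None:
        sag_fraction = float(sag["g_fraction"])
        tau_sag_ms = float(sag.get("tau_sag", 100.0))
        if not (0 <= sag_fraction < 1):
            raise ValueError("sag g_fraction must lie in [0, 1)")
        if step_duration < 1.0:
            raise ValueError("sag generation requires step_duration >= 1 s")
    dt = cfg.dt
    n_total = int(round((onset + step_duration + tail) / dt))
    n_on = int(round(onset / dt))
    n_step = int(round(step_duration / dt))
    if n_on + n_step > n_total:
        raise ValueError("step extends past the end of the sweep")

    t_step = np.arange(n_step) * dt
    f = _passive_shape(t_step, tau_s, sag_fraction, tau_sag_ms / 1e3)
    n_ss = int(round(0.2 / dt))
    f_peak = f.max()
    f_ss = f[-n_ss:].mean()
    truth_index = f_ss / f_peak

    sweeps, per_sweep = [], []
    for i, amp_pa in enumerate(step_amplitudes):
        dv_inf = amp_pa * rm * 1e-3  # pA * MΩ -> mV
        v = np.full(n_total, float(v_rest))
        v[n_on:n_on + n_step] = v_rest + dv_inf * f
        # post-step passive return to rest
        n_post = n_total - (n_on + n_step)
        if n_post > 0:
            v_end = v[n_on + n_step - 1]
            v[n_on + n_step:] = v_rest + (v_end - v_rest) * np.exp(
                -np.arange(1, n_post + 1) * dt / tau_s)
        v += _noise(cfg, cfg.rng(_TAG_PASSIVE, i), n_total)
        stim = StepProtocol(onset=onset, duration=step_duration, amplitude=amp_pa)
        sweeps.append(Sweep(samples=v, dt=dt, clamp_mode="current_clamp",
                            holding=0.0, stim=stim, sweep_id=f"step{i}"))
        per_sweep.append({
            "amplitude_pa": float(amp_pa),
            "v_hyp": float(v_rest + dv_inf * f_peak),
            "v_sag": float(v_rest + dv_inf * f_ss),
        })
    truth = GroundTruth(
        params={
            "rm_mohm": float(rm), "cm_pf": float(cm),
            "tau_m_ms": tau_s * 1e3, "v_rest_mv": float(v_rest),
            "sag_fraction": sag_fraction, "tau_sag_ms": tau_sag_ms,
            "sag_index": float(truth_index),
        },
        per_sweep=per_sweep,
    )
    return sweeps, truth


# ---------------------------------------------------------------------------
# action-potential trains


def _hermite(t, t_a, t_b, v_a, s_a, v_b, s_b):
    """Cubic Hermite between (t_a, v_a, slope s_a) and (t_b, v_b, slope s_b)."""
    T = t_b - t_a
    u = (t - t_a) / T
    h00 = 2 * u**3 - 3 * u**2 + 1
    h10 = u**3 - 2 * u**2 + u
    h01 = -2 * u**3 + 3 * u**2
    h11 = u**3 - u**2
    return v_a * h00 + T * s_a * h10 + v_b * h01 + T * s_b * h11


_SLOPE_AT_THRESHOLD = 10.0  # mV/ms, the operational spike-threshold criterion


@dataclass(frozen=True)
class _APShape:
    """Solved piecewise AP waveform, all times in ms relative to the
    threshold crossing (t = 0: V = threshold, dV/dt = 10 mV/ms exactly)."""

    threshold: float
    amplitude: float
    half_width: float
    ahp: float
    delta: float        # plateau depth below threshold, mV
    kappa: float        # d(dV/dt)/dt through threshold, mV/ms^2
    window: float       # half-width of the quadratic threshold window, ms
    t_foot: float       # foot duration, ms
    t_up: float         # upstroke duration (window end -> peak), ms
    t_down: float       # repolarization duration (peak -> trough), ms

    @property
    def t_peak(self) -> float:
        return self.window + self.t_up

    @property
    def start(self) -> float:
        return -(self.window + self.t_foot)

    @property
    def v_plateau(self) -> float:
        return self.threshold - self.delta

    def eval(self, t_ms: np.ndarray, t_rec: float) -> np.ndarray:
        """Evaluate the waveform; ``t_rec`` is the recovery duration (ms)."""
        thr, amp, ahp = self.threshold, self.amplitude, self.ahp
        W, k = self.window, self.kappa
        v_a = thr - _SLOPE_AT_THRESHOLD * W + k * W**2 / 2
        s_a = _SLOPE_AT_THRESHOLD - k * W
        v_b = thr + _SLOPE_AT_THRESHOLD * W + k * W**2 / 2
        s_b = _SLOPE_AT_THRESHOLD + k * W
        t_p = self.t_peak
        out = np.full_like(t_ms, self.v_plateau, dtype=float)

        m = (t_ms >= self.start) & (t_ms < -W)
        out[m] = _hermite(t_ms[m], self.start, -W, self.v_plateau, 0.0, v_a, s_a)
        m = (t_ms >= -W) & (t_ms < W)
        out[m] = thr + _SLOPE_AT_THRESHOLD * t_ms[m] + k * t_ms[m]**2 / 2
        m = (t_ms >= W) & (t_ms < t_p)
        out[m] = _hermite(t_ms[m], W, t_p, v_b, s_b, thr + amp, 0.0)
        m = (t_ms >= t_p) & (t_ms < t_p + self.t_down)
        v = (t_ms[m] - t_p) / self.t_down
        out[m] = (thr + amp) - (amp + ahp) * (3 * v**2 - 2 * v**3)
        m = (t_ms >= t_p + self.t_down) & (t_ms < t_p + self.t_down + t_rec)
        out[m] = _hermite(t_ms[m], t_p + self.t_down, t_p + self.t_down + t_rec,
                          thr - ahp, 0.0, self.v_plateau, 0.0)
        return out


def _solve_ap_shape(threshold: float, amplitude: float, half_width: float,
                    ahp: float, *, fall_rise_ratio: float = 2.0,
                    kappa: float = 60.0, window: float = 0.15,
                    delta: float = None) -> _APShape:
    """Find segment durations so the emitted half-width equals the parameter.

    The half-amplitude level sits on the upstroke Hermite segment and the
    cubic repolarization; both crossing offsets scale with the upstroke
    duration, which is solved by bracketing.
    """
    if amplitude <= 25.0:
        raise ValueError("AP amplitude must exceed 25 mV for reliable detection")
    if ahp < 0:
        raise ValueError("ahp must be >= 0")
    if delta is None:
        delta = min(8.0, 0.8 * ahp) if ahp > 0 else 8.0
    if kappa * window >= _SLOPE_AT_THRESHOLD:
        raise ValueError("kappa*window must stay below the threshold slope")
    W, k = window, kappa
    v_b = threshold + _SLOPE_AT_THRESHOLD * W + k * W**2 / 2
    s_b = _SLOPE_AT_THRESHOLD + k * W
    half_level = threshold + amplitude / 2
    drop = amplitude + ahp
    phi = (amplitude / 2) / drop
    v_f = brentq(lambda v: 3 * v**2 - 2 * v**3 - phi, 0.0, 1.0, xtol=1e-12)
    t_foot = 2.0

    def emitted_hw(t_up):
        t_p = W + t_up

        def rise(t):
            return _hermite(np.asarray([t]), W, t_p, v_b, s_b,
                            threshold + amplitude, 0.0)[0] - half_level

        t_half = brentq(rise, W, t_p - 1e-12, xtol=1e-12)
        t_down = fall_rise_ratio * (t_up + W)
        return (t_p - t_half) + v_f * t_down

    lo, hi = 0.02, 50.0
    if not (emitted_hw(lo) < half_width < emitted_hw(hi)):
        raise ValueError(f"half_width {half_width} ms is outside the "
                         "geometrically attainable range")
    t_up = brentq(lambda T: emitted_hw(T) - half_width, lo, hi, xtol=1e-12)
    return _APShape(threshold=threshold, amplitude=amplitude,
                    half_width=half_width, ahp=ahp, delta=delta, kappa=k,
                    window=W, t_foot=t_foot, t_up=t_up,
                    t_down=fall_rise_ratio * (t_up + W))


def gen_ap_train(cfg: SynthConfig, *, threshold: float = -41.9,
                 amplitude: float = 57.4, half_width: float = 0.74,
                 ahp: float = 10.3, isis: Sequence[float] = (25.0,) * 31,
                 step: float = 100.0, duration: float = 0.8,
                 v_rest: float = -60.0, stim_onset: float = 0.1,
                 first_delay: float = 25.0, tail: float = 0.1):
    """Current-clamp sweep with parametric action potentials on a plateau.

    Parameters (mV / ms): ``threshold`` is the voltage at which dV/dt crosses
    10 mV/ms, ``amplitude`` the peak above threshold, ``half_width`` the
    width at half-amplitude, ``ahp`` the positive trough depth below
    threshold. ``isis`` are peak-to-peak intervals in ms; the first peak sits
    ``first_delay`` ms after stimulus onset. ``step`` (pA) and ``duration``
    (s) describe the injected current for the stimulus metadata.

    Raises if consecutive AP waveforms would overlap.
    """
    dt = cfg.dt
    if half_width <= 2 * dt * 1e3:
        raise ValueError("half_width must exceed two sample intervals")
    shape = _solve_ap_shape(threshold, amplitude, half_width, ahp)
    peak_times = stim_onset + (first_delay + np.concatenate(
        [[0.0], np.cumsum(np.asarray(isis, float))])) * 1e-3
    if peak_times[-1] > stim_onset + duration + 1e-12:
        raise ValueError("spike train does not fit inside the stimulus duration")
    t0s = peak_times - shape.t_peak * 1e-3  # threshold-crossing times, s
    starts = t0s + shape.start * 1e-3
    if starts[0] < stim_onset + 0.01:
        raise ValueError("first AP foot begins too close to stimulus onset")

    n_total = int(round((stim_onset + duration + tail) / dt))
    t = np.arange(n_total) * dt
    v = np.full(n_total, float(v_rest))
    tau_on = 3e-3
    in_stim = t >= stim_onset
    v[in_stim] = shape.v_plateau + (v_rest - shape.v_plateau) * np.exp(
        -(t[in_stim] - stim_onset) / tau_on)

    fall_ends = t0s + (shape.t_peak + shape.t_down) * 1e-3
    recoveries = []
    for k in range(len(t0s)):
        next_start = starts[k + 1] if k + 1 < len(t0s) else t[-1]
        gap_ms = (next_start - fall_ends[k]) * 1e3 - 0.25
        t_rec = min(10.0, gap_ms)
        if t_rec < 1.0:
            raise ValueError(
                f"AP waveforms {k} and {k + 1} overlap (gap {gap_ms:.2f} ms)")
        recoveries.append(t_rec)

    for k, t0 in enumerate(t0s):
        end = fall_ends[k] + recoveries[k] * 1e-3
        sl = slice(int(math.ceil(starts[k] / dt - 1e-9)),
                   min(int(math.floor(end / dt + 1e-9)) + 1, n_total))
        rel_ms = (t[sl] - t0) * 1e3
        v[sl] = shape.eval(rel_ms, recoveries[k])

    # settle back to rest after the stimulus window
    n_stim_end = int(round((stim_onset + duration) / dt))
    last_end_idx = int(math.floor((fall_ends[-1] + recoveries[-1] * 1e-3) / dt)) + 1
    n_rel = max(n_stim_end, last_end_idx)
    if n_rel < n_total:
        v[n_rel:] = v_rest + (v[n_rel - 1] - v_rest) * np.exp(
            -np.arange(n_total - n_rel) * dt / 20e-3)

    v += _noise(cfg, cfg.rng(_TAG_AP, 0), n_total)
    stim = StepProtocol(onset=stim_onset, duration=duration, amplitude=step)
    sweep = Sweep(samples=v, dt=dt, clamp_mode="current_clamp",
                  holding=0.0, stim=stim, sweep_id="aptrain")
    isis_arr = np.asarray(isis, float)
    from .intrinsic import _adaptation_from_isis  # shared definition
    truth = GroundTruth(params={
        "threshold_mv": float(threshold), "amplitude_mv": float(amplitude),
        "half_width_ms": float(half_width), "ahp_mv": float(ahp),
        "peak_mv": float(threshold + amplitude),
        "peak_times_s": peak_times.tolist(),
        "isis_ms": isis_arr.tolist(),
        "n_spikes": int(len(peak_times)),
        "firing_frequency_hz": len(peak_times) / duration,
        "adaptation_ratio": _adaptation_from_isis(isis_arr),
    })
    return sweep, truth


# ---------------------------------------------------------------------------
# synaptic traces


def _biexp_unit_peak(t: np.ndarray, tau_rise_ms: float,
                     tau_decay_ms: float) -> np.ndarray:
    """Difference-of-exponentials conductance shape with unit peak."""
    tr, td = tau_rise_ms * 1e-3, tau_decay_ms * 1e-3
    if tr >= td:
        raise ValueError("tau_rise must be smaller than tau_decay")
    t_pk = math.log(td / tr) * tr * td / (td - tr)
    norm = math.exp(-t_pk / td) - math.exp(-t_pk / tr)
    out = np.zeros_like(t)
    m = t >= 0
    out[m] = (np.exp(-t[m] / td) - np.exp(-t[m] / tr)) / norm
    return out


_COMPONENT_DEFAULTS = {
    # tau_rise, tau_decay (ms): slow GABA_A vs fast AMPA kinetics
    "gaba": (0.8, 9.0),
    "ampa": (0.2, 2.0),
}


def gen_synaptic_trace(cfg: SynthConfig, *,
                       pulse_times: Sequence[float],
                       g_gaba: float = 1.0, g_ampa: float = 0.0,
                       tau_rise_gaba: float = None, tau_decay_gaba: float = None,
                       tau_rise_ampa: float = None, tau_decay_ampa: float = None,
                       e_gaba: float = -60.0, e_ampa: float = 0.0,
                       v_hold: float = -40.0,
                       failure_p: float = 0.0, cv_q: float = 0.0,
                       depression_f: float = 1.0,
                       async_fraction_by_pulse: Optional[Sequence[float]] = None,
                       async_window: float = 15.0,
                       latency: float = 1.0, latency_jitter: float = 0.2,
                       duration: Optional[float] = None,
                       n_sweeps: int = 1, sweep_offset: int = 0):
    """Voltage-clamp PSC trace(s) with per-event ground truth.

    Per pulse and component: a Bernoulli success draw (failure probability
    ``failure_p``), a lognormal quantal scale (CV ``cv_q``, mean 1),
    multiplicative short-term depression (``depression_f`` per preceding
    success of that component), and a release time — synchronous (fixed
    ``latency`` ms plus Gaussian jitter) or, with per-pulse probability
    ``async_fraction_by_pulse[i]``, asynchronous (uniform within the
    ``async_window`` ms ending at the next pulse onset). The summed current
    is ``sum_i g_i(t) * (v_hold - E_i)`` in pA with conductances in nS and
    potentials in mV; inward currents are negative.

    Returns ``(sweeps, GroundTruth)``; truth lists every event's pulse index,
    component, release time, conductance and peak current, plus failures.
    """
    if not (0 <= failure_p < 1):
        raise ValueError("failure_p must lie in [0, 1)")
    pulse_times = np.asarray(pulse_times, float)
    if pulse_times.ndim != 1 or pulse_times.size == 0:
        raise ValueError("pulse_times must be a non-empty sequence")
    if np.any(np.diff(pulse_times) <= 0):
        raise ValueError("pulse_times must be strictly increasing")
    for comp, g, e in (("gaba", g_gaba, e_gaba), ("ampa", g_ampa, e_ampa)):
        if g > 0 and abs(v_hold - e) < 1e-9:
            raise ValueError(f"{comp} reversal equals v_hold; component invisible")
    period = float(np.median(np.diff(pulse_times))) if pulse_times.size > 1 else 0.02
    if async_fraction_by_pulse is not None:
        frac = np.asarray(async_fraction_by_pulse, float)
        if frac.size != pulse_times.size:
            raise ValueError("async_fraction_by_pulse must match pulse count")
        if np.any((frac < 0) | (frac > 1)):
            raise ValueError("async fractions must lie in [0, 1]")
        if async_window * 1e-3 > period + 1e-12:
            raise ValueError("async window longer than the inter-pulse interval")
    else:
        frac = np.zeros(pulse_times.size)

    kinetics = {
        "gaba": (tau_rise_gaba or _COMPONENT_DEFAULTS["gaba"][0],
                 tau_decay_gaba or _COMPONENT_DEFAULTS["gaba"][1]),
        "ampa": (tau_rise_ampa or _COMPONENT_DEFAULTS["ampa"][0],
                 tau_decay_ampa or _COMPONENT_DEFAULTS["ampa"][1]),
    }
    conductances = {"gaba": (g_gaba, e_gaba), "ampa": (g_ampa, e_ampa)}
    max_decay = max(kinetics[c][1] for c in kinetics)
    if duration is None:
        duration = pulse_times[-1] + period + 10 * max_decay * 1e-3
    dt = cfg.dt
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    if cv_q > 0:
        sigma = math.sqrt(math.log(1 + cv_q**2))
        mu = -sigma**2 / 2  # mean-1 lognormal
    sweeps, per_sweep = [], []
    for s_idx in range(n_sweeps):
        rng = cfg.rng(_TAG_SYN, sweep_offset + s_idx)
        current = np.zeros(n)
        events = []
        n_success = {"gaba": 0, "ampa": 0}
        for i, p in enumerate(pulse_times):
            next_onset = pulse_times[i + 1] if i + 1 < pulse_times.size else p + period
            for comp in ("gaba", "ampa"):
                g0, e_rev = conductances[comp]
                if g0 <= 0:
                    continue
                fail = rng.random() < failure_p
                q = rng.lognormal(mu, sigma) if cv_q > 0 else 1.0
                is_async = rng.random() < frac[i]
                u_async = rng.uniform(next_onset - async_window * 1e-3, next_onset)
                jit = rng.normal(0.0, latency_jitter * 1e-3)
                if fail:
                    events.append({"pulse": i, "component": comp,
                                   "failure": True, "time_s": None,
                                   "g_ns": 0.0, "peak_pa": 0.0, "mode": None})
                    continue
                g = g0 * q * depression_f**n_success[comp]
                n_success[comp] += 1
                t_rel = u_async if is_async else p + latency * 1e-3 + jit
                tr, td = kinetics[comp]
                current += g * (v_hold - e_rev) * _biexp_unit_peak(t - t_rel, tr, td)
                events.append({
                    "pulse": i, "component": comp, "failure": False,
                    "time_s": float(t_rel), "g_ns": float(g),
                    "peak_pa": float(g * (v_hold - e_rev)),
                    "mode": "async" if is_async else "sync",
                })
        current += _noise(cfg, rng, n)
        stim = StepProtocol(onset=float(pulse_times[0]), duration=0.0,
                            amplitude=0.0, pulse_times=tuple(pulse_times),
                            pulse_rate=(1.0 / period if period > 0 else None))
        sweeps.append(Sweep(samples=current, dt=dt, clamp_mode="voltage_clamp",
                            holding=v_hold, stim=stim,
                            sweep_id=f"syn{sweep_offset + s_idx}"))
        per_sweep.append({"events": events})
    truth = GroundTruth(
        params={
            "g_gaba_ns": float(g_gaba), "g_ampa_ns": float(g_ampa),
            "e_gaba_mv": float(e_gaba), "e_ampa_mv": float(e_ampa),
            "v_hold_mv": float(v_hold), "failure_p": float(failure_p),
            "cv_q": float(cv_q), "depression_f": float(depression_f),
            "kinetics_ms": {c: list(kinetics[c]) for c in kinetics},
            "latency_ms": float(latency),
            "latency_jitter_ms": float(latency_jitter),
            "async_fraction_by_pulse": frac.tolist(),
            "async_window_ms": float(async_window),
            "pulse_times_s": pulse_times.tolist(),
        },
        per_sweep=per_sweep,
    )
    return sweeps, truth


def gen_dsi_epochs(cfg: SynthConfig, *, g_gaba: float = 2.0,
                   suppression_pct: float = 75.0, recovery_pct: float = 95.0,
                   n_events: int = 8, v_hold: float = -70.0,
                   e_gaba: float = 0.0, **kwargs):
    """Unitary IPSC sweeps for the three DSI epochs (control / DSI / recovery).

    Emulates the depolarization-to-0-mV protocol: GABA release is scaled to
    ``(1 - suppression_pct/100)`` during the DSI epoch and back to
    ``recovery_pct/100`` afterwards. Returns ``{condition: (sweeps, truth)}``.
    """
    out = {}
    scales = {"ctl": 1.0, "dsi": 1.0 - suppression_pct / 100.0,
              "recovery": recovery_pct / 100.0}
    offset = 0
    for cond, scale in scales.items():
        sweeps, truth = gen_synaptic_trace(
            cfg, pulse_times=[0.05], g_gaba=g_gaba * scale, g_ampa=0.0,
            v_hold=v_hold, e_gaba=e_gaba, n_sweeps=n_events,
            sweep_offset=offset, **kwargs)
        truth.params["condition"] = cond
        truth.params["scale"] = scale
        out[cond] = (sweeps, truth)
        offset += n_events
    return out


# ---------------------------------------------------------------------------
# field potentials


def gen_lfp(cfg: SynthConfig, *, f0: float = 40.0, amp: float = 0.1,
            duration: float = 10.0, broadband_sd: float = 0.02,
            extra_tones: Sequence = ()) -> Sweep:
    """Gamma-band LFP epoch: sinusoid at ``f0`` (mV amplitude ``amp``) plus
    white noise, emulating carbachol-induced oscillations. ``extra_tones``
    is a sequence of ``(freq_hz, amplitude_mv)`` pairs added on top."""
    nyquist = 0.5 / cfg.dt
    if not (0 < f0 < nyquist):
        raise ValueError(f"f0 must lie in (0, {nyquist}) Hz")
    if duration < 10.0:
        warnings.warn("LFP epochs shorter than the 10 s protocol epoch",
                      stacklevel=2)
    n = int(round(duration / cfg.dt))
    t = np.arange(n) * cfg.dt
    v = amp * np.sin(2 * np.pi * f0 * t)
    for f_x, a_x in extra_tones:
        v = v + a_x * np.sin(2 * np.pi * f_x * t)
    rng = cfg.rng(_TAG_LFP, 0)
    if broadband_sd > 0:
        v = v + rng.normal(0.0, broadband_sd, n)
    return Sweep(samples=v, dt=cfg.dt, clamp_mode="field", holding=0.0,
                 sweep_id="lfp")
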