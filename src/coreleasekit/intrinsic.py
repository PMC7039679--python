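"""Intrinsic membrane and action-potential properties from current-clamp sweeps.

Implements the standard slice-physiology estimators: resting potential from
the pre-stimulus baseline, input resistance by linear regression of
steady-state voltage deflections (within +/-15 mV of rest) against injected
current, membrane time constant by single-exponential fit to averaged -20 pA
pulses, sag index interpolated to the current giving V_sag = -80 mV from
polynomial V-I fits, spike detection at the 10 mV/ms dV/dt criterion, and
per-spike waveform features (threshold, amplitude, half-width with
sub-sample interpolation, maximal slopes, AHP).

All voltages mV, currents pA, resistances MΩ, times of spike events s,
kinetic quantities ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .trace_io import Sweep

__all__ = [
    "MembraneProperties",
    "SpikeTrain",
    "APFeatures",
    "resting_potential",
    "input_resistance",
    "time_constant",
    "sag_index",
    "detect_spikes",
    "ap_features",
    "train_stats",
]

SLOPE_CRITERION = 10.0   # mV/ms — operational AP threshold
PEAK_MARGIN = 20.0       # mV above onset required of the following peak
PEAK_SEARCH_MS = 2.0     # window after the slope crossing to find the peak
REFRACTORY_MS = 1.0
SS_WINDOW_S = 0.2        # steady-state window: last 200 ms of a step


@dataclass
class MembraneProperties:
    """One cell's intrinsic-parameter record (the per-cell summary row)."""

    v_rest: Optional[float] = None            # mV
    r_m: Optional[float] = None               # MΩ
    tau_m: Optional[float] = None             # ms
    c_m: Optional[float] = None               # pF
    sag_index: Optional[float] = None
    spike_threshold: Optional[float] = None   # mV
    spike_amplitude: Optional[float] = None   # mV
    half_width: Optional[float] = None        # ms
    max_rise_slope: Optional[float] = None    # mV/ms
    max_decay_slope: Optional[float] = None   # mV/ms
    ahp: Optional[float] = None               # mV (threshold minus trough)
    firing_frequency: Optional[float] = None  # Hz
    adaptation_ratio: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class SpikeTrain:
    spike_times: np.ndarray       # peak times, s
    isis: np.ndarray              # interspike intervals, ms
    window: tuple                 # (start, end) of the stimulus, s

    @property
    def n_spikes(self) -> int:
        return int(len(self.spike_times))


@dataclass
class APFeatures:
    threshold: float
    amplitude: float
    half_width: float
    max_rise: float
    max_decay: float
    ahp: Optional[float]
    peak_time: float
    onset_time: float


def _slope_mv_per_ms(sweep: Sweep) -> np.ndarray:
    """Central-difference dV/dt on the raw trace, in mV/ms."""
    return np.gradient(sweep.samples, sweep.dt) * 1e-3


def _baseline(sweep: Sweep, min_s: float = 0.1) -> float:
    if sweep.stim is None or sweep.stim.onset < min_s:
        raise ValueError(
            f"need >= {min_s * 1e3:.0f} ms of pre-stimulus baseline "
            "(stimulus metadata missing or onset too early)")
    n = int(round(sweep.stim.onset / sweep.dt))
    return float(sweep.samples[:n].mean())


def resting_potential(sweep: Sweep) -> float:
    """Mean of the pre-stimulus baseline, mV (>= 100 ms required)."""
    return _baseline(sweep)


def _step_slices(sweep: Sweep):
    st = sweep.stim
    i0 = int(round(st.onset / sweep.dt))
    i1 = int(round((st.onset + st.duration) / sweep.dt))
    n_ss = int(round(SS_WINDOW_S / sweep.dt))
    n_ss = min(n_ss, i1 - i0)
    return i0, i1, n_ss


def input_resistance(sweeps: Sequence[Sweep], max_deflection: float = 15.0):
    """Input resistance (MΩ) by OLS of steady-state deflection vs current.

    The steady-state deflection of each step is the mean over the last
    200 ms of the step minus the sweep's own baseline; steps deflecting more
    than ``max_deflection`` mV from rest are excluded before fitting, and at
    least three qualifying steps are required.
    """
    currents, deflections, excluded = [], [], []
    for sw in sweeps:
        if sw.stim is None or sw.stim.duration <= 0:
            raise ValueError(f"sweep {sw.sweep_id!r} lacks step metadata")
        base = _baseline(sw)
        i0, i1, n_ss = _step_slices(sw)
        dv = float(sw.samples[i1 - n_ss:i1].mean() - base)
        if abs(dv) > max_deflection:
            excluded.append((sw.sweep_id, dv))
            continue
        currents.append(sw.stim.amplitude)
        deflections.append(dv)
    if len(currents) < 3:
        raise ValueError(
            f"fewer than 3 steps within +/-{max_deflection} mV of rest "
            f"(excluded: {excluded})")
    slope = np.polyfit(np.asarray(currents), np.asarray(deflections), 1)[0]
    return float(slope * 1e3)  # mV/pA = GΩ -> MΩ


def time_constant(sweeps: Sequence[Sweep], r_m: Optional[float] = None,
                  tau_bounds_ms=(0.5, 200.0)):
    """Membrane time constant from averaged hyperpolarizing pulses.

    Averages the repeats (identical timing required), then least-squares
    fits ``V(t) = V0 + dV*(1 - exp(-t/tau))`` from pulse onset over five
    initial-guess time constants. Returns ``(tau_ms, c_m_pf)``; capacitance
    ``c_m = tau/r_m`` is computed when ``r_m`` (MΩ) is supplied, else None.
    """
    ref = sweeps[0]
    for sw in sweeps[1:]:
        if (sw.n_samples != ref.n_samples or sw.dt != ref.dt
                or sw.stim is None or ref.stim is None
                or sw.stim.onset != ref.stim.onset
                or sw.stim.duration != ref.stim.duration):
            raise ValueError("pulse repeats must share timing and length")
    mean = np.mean([sw.samples for sw in sweeps], axis=0)
    avg = Sweep(samples=mean, dt=ref.dt, clamp_mode=ref.clamp_mode,
                holding=ref.holding, stim=ref.stim, sweep_id="avg")
    base = _baseline(avg)
    i0, i1, n_ss = _step_slices(avg)
    dv_ss = float(mean[i1 - n_ss:i1].mean() - base)
    if abs(dv_ss) < 1e-9:
        raise ValueError("no measurable deflection to fit")
    # initial tau guess: time to reach 63.2% of the steady-state deflection
    seg = mean[i0:i1] - base
    frac = seg / dv_ss
    above = np.nonzero(frac >= 1 - math.exp(-1))[0]
    tau_guess = (above[0] if above.size else (i1 - i0) / 5) * ref.dt
    tau_guess = max(tau_guess, 2 * ref.dt)
    n_fit = min(int(round(5 * tau_guess / ref.dt)), i1 - i0)
    t = np.arange(n_fit) * ref.dt
    y = mean[i0:i0 + n_fit]

    def model(tt, v0, dv, tau):
        return v0 + dv * (1 - np.exp(-tt / tau))

    try:
        popt, _ = curve_fit(model, t, y, p0=(base, dv_ss, tau_guess),
                            maxfev=10000)
    except RuntimeError as exc:
        raise ValueError(f"exponential fit did not converge: {exc}") from exc
    tau_ms = float(popt[2] * 1e3)
    if not (tau_bounds_ms[0] < tau_ms < tau_bounds_ms[1]):
        raise ValueError(f"fitted tau {tau_ms:.2f} ms outside "
                         f"{tau_bounds_ms} ms — fit rejected")
    c_m = tau_ms / r_m * 1e3 if r_m else None  # ms/MΩ -> nF -> pF
    return tau_ms, c_m


def sag_index(sweeps: Sequence[Sweep], v_rest: float,
              v_sag_target: float = -80.0, hyp_smooth_ms: float = 2.0) -> float:
    """Sag index at the current giving V_sag = ``v_sag_target``.

    Per hyperpolarizing step, V_hyp is the most negative voltage during the
    step and V_sag the mean over its last 200 ms. Because the sag trough is
    a slow event (membrane time constant ~20 ms), V_hyp is read from a
    lightly smoothed copy of the trace (``hyp_smooth_ms`` boxcar) — the raw
    per-sample minimum would carry an extreme-value noise bias of several
    noise SDs over a 2 s step. Both V-I relations are fit
    with cubic polynomials (quadratic when fewer than five steps); the
    current at which the fitted V_sag equals the target is solved for within
    the sampled range (no extrapolation), and the index is
    ``(v_rest - V_sag) / (v_rest - V_hyp)`` at that current.
    """
    currents, v_hyp, v_sag = [], [], []
    for sw in sweeps:
        if sw.stim is None or sw.stim.amplitude >= 0:
            continue
        i0, i1, n_ss = _step_slices(sw)
        currents.append(sw.stim.amplitude)
        n_sm = max(int(round(hyp_smooth_ms * 1e-3 / sw.dt)), 1)
        smoothed = np.convolve(sw.samples[i0:i1], np.full(n_sm, 1.0 / n_sm),
                               mode="valid")
        v_hyp.append(float(smoothed.min()))
        v_sag.append(float(sw.samples[i1 - n_ss:i1].mean()))
    if len(currents) < 4:
        raise ValueError("need >= 4 hyperpolarizing steps for sag index")
    currents = np.asarray(currents)
    v_hyp = np.asarray(v_hyp)
    v_sag = np.asarray(v_sag)
    if not (v_sag.min() <= v_sag_target <= v_sag.max()):
        raise ValueError(
            f"target V_sag {v_sag_target} mV outside the sampled range "
            f"[{v_sag.min():.1f}, {v_sag.max():.1f}] — refusing to extrapolate")
    order = 3 if len(currents) >= 5 else 2
    p_sag = np.polyfit(currents, v_sag, order)
    p_hyp = np.polyfit(currents, v_hyp, order)
    shifted = p_sag.copy()
    shifted[-1] -= v_sag_target
    roots = np.roots(shifted)
    real = roots[np.abs(roots.imag) < 1e-9].real
    in_range = real[(real >= currents.min() - 1e-9) & (real <= currents.max() + 1e-9)]
    if in_range.size == 0:
        raise ValueError("fitted V_sag never reaches the target within the "
                         "sampled current range")
    i_star = float(in_range[np.argmin(np.abs(in_range))])
    vs = float(np.polyval(p_sag, i_star))
    vh = float(np.polyval(p_hyp, i_star))
    return (v_rest - vs) / (v_rest - vh)


# ---------------------------------------------------------------------------
# spikes


def detect_spikes(sweep: Sweep) -> SpikeTrain:
    """Detect action potentials via the 10 mV/ms slope criterion.

    A spike onset is an upward crossing of dV/dt = 10 mV/ms followed within
    2 ms by a local maximum at least 20 mV above the onset voltage; spikes
    are time-stamped at that peak, with a 1 ms refractory exclusion. An
    empty train is a valid result.
    """
    if sweep.dt > 1e-4:
        raise ValueError("spike detection requires sampling at dt <= 0.1 ms")
    v = sweep.samples
    dt = sweep.dt
    slope = _slope_mv_per_ms(sweep)
    crossings = np.nonzero((slope[:-1] < SLOPE_CRITERION)
                           & (slope[1:] >= SLOPE_CRITERION))[0]
    n_peak = int(round(PEAK_SEARCH_MS * 1e-3 / dt))
    peaks = []
    last_peak = -math.inf
    for k in crossings:
        frac = (SLOPE_CRITERION - slope[k]) / (slope[k + 1] - slope[k])
        v_onset = v[k] + frac * (v[k + 1] - v[k])
        hi = min(k + 1 + n_peak, len(v))
        if hi - (k + 1) < 2:
            continue
        seg = v[k + 1:hi]
        p_rel = int(np.argmax(seg))
        p = k + 1 + p_rel
        if v[p] < v_onset + PEAK_MARGIN:
            continue
        if p + 1 < len(v) and v[p + 1] > v[p]:  # still rising at window end
            continue
        t_peak = p * dt
        if t_peak - last_peak < REFRACTORY_MS * 1e-3:
            continue
        peaks.append(t_peak)
        last_peak = t_peak
    if sweep.stim is not None and sweep.stim.duration > 0:
        window = (sweep.stim.onset, sweep.stim.onset + sweep.stim.duration)
        peaks = [t for t in peaks if window[0] <= t <= window[1] + dt / 2]
    else:
        window = (0.0, sweep.duration)
    times = np.asarray(peaks)
    isis = np.diff(times) * 1e3
    return SpikeTrain(spike_times=times, isis=isis, window=window)


def ap_features(sweep: Sweep, spike_time: float, *,
                next_spike_time: Optional[float] = None,
                ahp_window_ms: float = 20.0,
                onset_search_ms: float = 5.0) -> APFeatures:
    """Waveform features of one detected spike.

    threshold — voltage at the 10 mV/ms upward crossing (linear
    interpolation between samples); amplitude — peak minus threshold;
    half_width — time between the two crossings of threshold +
    amplitude/2, interpolated; max_rise / max_decay — extrema of dV/dt
    between onset and trough; ahp — threshold minus the most negative
    voltage within 20 ms of the peak (or until the next spike's onset),
    None when the sweep ends before the trough is reached.
    """
    v = sweep.samples
    dt = sweep.dt
    slope = _slope_mv_per_ms(sweep)
    k_p = int(round(spike_time / dt))
    lo = max(k_p - 2, 0)
    k_p = lo + int(np.argmax(v[lo:min(k_p + 3, len(v))]))
    n_back = int(round(onset_search_ms * 1e-3 / dt))
    j = None
    for k in range(k_p - 1, max(k_p - n_back, 0) - 1, -1):
        if slope[k] < SLOPE_CRITERION <= slope[k + 1]:
            j = k
            break
    if j is None:
        raise ValueError("no 10 mV/ms onset found before the given peak")
    frac = (SLOPE_CRITERION - slope[j]) / (slope[j + 1] - slope[j])
    onset_time = (j + frac) * dt
    threshold = float(v[j] + frac * (v[j + 1] - v[j]))
    amplitude = float(v[k_p] - threshold)
    half = threshold + amplitude / 2

    def interp_crossing(k0, k1, rising):
        rng = range(k0, k1) if rising else range(k0, k1)
        for k in rng:
            a, b = v[k], v[k + 1]
            if (rising and a < half <= b) or (not rising and a >= half > b):
                return (k + (half - a) / (b - a)) * dt
        return None

    t_up = interp_crossing(j, k_p, rising=True)
    n_fwd = int(round(ahp_window_ms * 1e-3 / dt))
    end = min(k_p + n_fwd, len(v) - 1)
    if next_spike_time is not None:
        end = min(end, int(next_spike_time / dt))
    t_down = interp_crossing(k_p, end, rising=False)
    if t_up is None or t_down is None:
        raise ValueError("half-amplitude crossings not found around the peak")
    half_width = (t_down - t_up) * 1e3

    trough_rel = int(np.argmin(v[k_p:end + 1]))
    k_t = k_p + trough_rel
    truncated = (end == len(v) - 1) and (k_t == end)
    ahp = None if truncated else float(threshold - v[k_t])
    max_rise = float(slope[j:k_t + 1].max())
    max_decay = float(slope[j:k_t + 1].min())
    return APFeatures(threshold=threshold, amplitude=amplitude,
                      half_width=half_width, max_rise=max_rise,
                      max_decay=max_decay, ahp=ahp,
                      peak_time=k_p * dt, onset_time=onset_time)


def _adaptation_from_isis(isis: np.ndarray) -> Optional[float]:
    """Late-ISI mean over first ISI: last 3 ISIs when >= 5 exist, last 2 for
    2-4 ISIs, undefined below that."""
    isis = np.asarray(isis, float)
    if isis.size < 2:
        return None
    n_late = 3 if isis.size >= 5 else 2
    return float(isis[-n_late:].mean() / isis[0])


def train_stats(train: SpikeTrain):
    """Firing frequency (spikes / stimulus duration, Hz) and adaptation
    ratio; the ratio is None when fewer than three spikes exist."""
    t0, t1 = train.window
    freq = train.n_spikes / (t1 - t0)
    return freq, _adaptation_from_isis(train.isis)


def membrane_properties(*, step_sweeps=None, tau_sweeps=None,
                        rheobase_sweep=None, train_sweep=None,
                        v_rest: Optional[float] = None) -> MembraneProperties:
    """Assemble a full per-cell property record from sweep families.

    Any family may be omitted; the corresponding fields stay None. ``v_rest``
    defaults to the baseline of the first available current-clamp sweep.
    """
    props = MembraneProperties()
    first = next((s[0] for s in (step_sweeps, tau_sweeps) if s),
                 rheobase_sweep or train_sweep)
    if v_rest is None and first is not None:
        v_rest = resting_potential(first)
    props.v_rest = v_rest
    if step_sweeps:
        props.r_m = input_resistance(step_sweeps)
        try:
            props.sag_index = sag_index(step_sweeps, v_rest)
        except ValueError:
            pass
    if tau_sweeps:
        props.tau_m, props.c_m = time_constant(tau_sweeps, r_m=props.r_m)
    if rheobase_sweep is not None:
        train = detect_spikes(rheobase_sweep)
        if train.n_spikes:
            nxt = (train.spike_times[1] if train.n_spikes > 1 else None)
            f = ap_features(rheobase_sweep, train.spike_times[0],
                            next_spike_time=nxt)
            props.spike_threshold = f.threshold
            props.spike_amplitude = f.amplitude
            props.half_width = f.half_width
            props.max_rise_slope = f.max_rise
            props.max_decay_slope = f.max_decay
            props.ahp = f.ahp
    if train_sweep is not None:
        train = detect_spikes(train_sweep)
        props.firing_frequency, props.adaptation_ratio = train_stats(train)
    return props
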