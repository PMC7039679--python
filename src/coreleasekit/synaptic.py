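"""Unitary and optogenetically evoked PSC quantification.

Covers the per-connection synaptic statistics (amplitude including failures,
potency excluding them, failure rate, paired-pulse ratio, coefficient of
variation, latency, rise/decay kinetics), the Nernst reversal-potential
calculation from pipette/bath solution recipes, conversion of peak currents
to conductances, polarity-based dissociation of GABAergic (outward at a
holding potential above E_Cl) and glutamatergic (inward, E_rev near 0 mV)
components, and depolarization-induced suppression of inhibition (DSI).

Sign convention: inward currents negative, outward positive; conductances
are reported positive with a component label.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .trace_io import Sweep

__all__ = [
    "EventMeasurement",
    "UnitaryEventStats",
    "ConductanceResult",
    "DSIResult",
    "nernst",
    "ion_concentration",
    "measure_events",
    "unitary_stats",
    "event_kinetics",
    "to_conductance",
    "split_components",
    "dsi",
]

R_GAS = 8.31446261815324      # J / (mol K)
FARADAY = 96485.33212331      # C / mol


def _detection_threshold(sd_smoothed: float, k: float, n_search: int,
                         n_smooth: int) -> float:
    """Event-detection threshold with an extreme-value correction.

    The peak is searched over ``n_search`` samples whose smoothed values are
    correlated over ``n_smooth`` samples, i.e. roughly m = n_search/n_smooth
    independent draws; the expected extremum of pure noise grows like
    sqrt(2 ln 2m) SDs, so ``k`` SDs is applied on top of that scale —
    otherwise the window maximum of noise alone would routinely clear a
    plain k*SD bar.
    """
    m = max(n_search // max(n_smooth, 1), 1)
    return k * sd_smoothed * math.sqrt(2.0 * math.log(2.0 * m))


@dataclass
class EventMeasurement:
    """One evoked response on one trial: signed peak, failure flag, latency
    (pulse to 10%-of-peak onset, ms) and onset-slope polarity."""

    trial: int
    pulse: int
    amplitude: float                  # pA, signed; 0 for failures
    is_failure: bool
    latency: Optional[float] = None   # ms, None for failures
    polarity: Optional[str] = None    # "inward" | "outward"


@dataclass
class UnitaryEventStats:
    amplitude: Optional[float]        # mean incl. failures, pA
    potency: Optional[float]          # mean excl. failures, pA
    failure_rate: float
    cv: Optional[float]
    ppr: Optional[float]
    latency_mean: Optional[float]     # ms
    latency_sd: Optional[float]       # ms
    rise_time: Optional[float] = None  # ms, 20-80%
    decay_tau: Optional[float] = None  # ms


@dataclass
class ConductanceResult:
    g: float                # nS, >= 0
    v_hold: float           # mV
    e_rev: float            # mV
    component: str          # "GABA" | "Glu"


@dataclass
class DSIResult:
    ctl_amplitude: float
    dsi_amplitude: float
    recovery_amplitude: Optional[float]
    suppression: float      # percent, 100*(1 - dsi/ctl)


# ---------------------------------------------------------------------------
# Nernst


def ion_concentration(solution: dict, ion: str) -> float:
    """Total concentration (mM) of ``ion`` summed over all salts.

    Salt names are read as chemical formulas: the ion symbol followed by an
    optional count, not followed by a lowercase letter (so ``Cl`` matches
    KCl, MgCl2, CaCl2 but not e.g. a name containing "Chloride"). Organic
    counter-ions (gluconate, methanesulfonate, HEPES, ...) contribute
    nothing to inorganic ion totals, as intended.
    """
    pat = re.compile(re.escape(ion) + r"(?![a-z])(\d*)")
    total = 0.0
    for salt, conc in solution.items():
        count = sum(int(m or "1") for m in pat.findall(salt))
        total += count * conc
    return total


def nernst(internal: dict, external: dict, ion: str = "Cl", z: int = -1,
           temperature: float = 33.0) -> float:
    """Nernst equilibrium potential, mV: (RT / zF) * ln([out]/[in]).

    ``internal`` and ``external`` map salt names to concentrations in mM
    (e.g. the K-gluconate pipette recipe ``{"K-gluconate": 130, "KCl": 5,
    "MgCl2": 3, ...}`` against recording aCSF); the ion's total is summed
    across salts on each side. ``temperature`` in degrees Celsius.
    """
    c_in = ion_concentration(internal, ion)
    c_out = ion_concentration(external, ion)
    if c_in <= 0 or c_out <= 0:
        raise ValueError(
            f"[{ion}] must be positive on both sides (in={c_in}, out={c_out} mM)")
    t_kelvin = temperature + 273.15
    return (R_GAS * t_kelvin / (z * FARADAY)) * math.log(c_out / c_in) * 1e3


# ---------------------------------------------------------------------------
# event measurement


def measure_events(post: Sweep, pulse_times: Sequence[float], *,
                   window: float = 15.0, baseline: float = 10.0,
                   polarity: str = "auto", failure_k: float = 3.0,
                   trial: int = 0) -> list:
    """Measure one evoked response per pulse on a voltage-clamp sweep.

    Per pulse the extremum within ``window`` ms after the pulse is taken
    (signed; ``polarity`` forces "inward"/"outward" or "auto" picks the
    larger excursion), relative to a local pre-pulse baseline (the 2 ms
    before each pulse) so that within-train summation on the tail of the
    preceding response does not inflate later amplitudes.

    The success/failure decision is made on a 0.5 ms boxcar-smoothed copy:
    a trial fails when the smoothed extremum does not exceed ``failure_k``
    times the smoothed baseline noise SD. (On the raw trace the expected
    extremum of pure noise over a multi-ms window already exceeds 3 SD, so
    the raw criterion would misclassify most failures; smoothing restores
    the intended operating point.) Failures are recorded with amplitude 0 so
    that mean-including-failures arithmetic is exact. Latency is pulse time
    to the first crossing of 10% of the peak.
    """
    pulse_times = np.asarray(pulse_times, float)
    if pulse_times.size == 0:
        raise ValueError("no pulse times supplied")
    dt = post.dt
    if pulse_times.size > 1:
        min_ipi = np.diff(pulse_times).min()
        if window * 1e-3 > min_ipi + 1e-12:
            raise ValueError(
                f"window {window} ms overlaps the next pulse "
                f"(inter-pulse interval {min_ipi * 1e3:.1f} ms)")
    n_base = int(round(baseline * 1e-3 / dt))
    i_first = int(round(pulse_times[0] / dt))
    if i_first - n_base < 0:
        raise ValueError("baseline window precedes the first pulse")
    n_sm = max(int(round(0.5e-3 / dt)), 1)
    smoothed = np.convolve(post.samples, np.full(n_sm, 1.0 / n_sm),
                           mode="same")
    sm_base_seg = smoothed[i_first - n_base:i_first]
    sm_noise_sd = float(sm_base_seg.std(ddof=1)) if n_base > 1 else 0.0
    n_local = max(int(round(min(2.0, baseline) * 1e-3 / dt)), 1)

    out = []
    n_win = int(round(window * 1e-3 / dt))
    for ip, p in enumerate(pulse_times):
        i0 = int(round(p / dt))
        local_base = float(post.samples[max(i0 - n_local, 0):i0].mean())
        seg = post.samples[i0:min(i0 + n_win, post.n_samples)] - local_base
        if seg.size == 0:
            raise ValueError(f"pulse {ip} lies outside the sweep")
        if polarity == "inward":
            k_pk = int(np.argmin(seg))
        elif polarity == "outward":
            k_pk = int(np.argmax(seg))
        elif polarity == "auto":
            k_pk = int(np.argmax(np.abs(seg)))
        else:
            raise ValueError("polarity must be 'inward', 'outward' or 'auto'")
        peak = float(seg[k_pk])
        sm_seg = smoothed[i0:i0 + seg.size] - float(
            smoothed[max(i0 - n_local, 0):i0].mean())
        sm_peak = sm_seg[np.argmax(np.abs(sm_seg))]
        if abs(sm_peak) <= _detection_threshold(sm_noise_sd, failure_k,
                                                seg.size, n_sm):
            out.append(EventMeasurement(trial=trial, pulse=ip, amplitude=0.0,
                                        is_failure=True))
            continue
        thresh = 0.1 * peak
        onset_idx = None
        for k in range(k_pk + 1):
            if (peak > 0 and seg[k] >= thresh) or (peak < 0 and seg[k] <= thresh):
                onset_idx = k
                break
        latency = (onset_idx if onset_idx is not None else k_pk) * dt * 1e3
        out.append(EventMeasurement(
            trial=trial, pulse=ip, amplitude=peak, is_failure=False,
            latency=latency, polarity="outward" if peak > 0 else "inward"))
    return out


def unitary_stats(first_events: Sequence[EventMeasurement],
                  second_events: Optional[Sequence[EventMeasurement]] = None,
                  min_trials: int = 10) -> UnitaryEventStats:
    """Per-connection summary over consecutive trials of the first (and
    optionally second) pulse.

    amplitude — mean over all trials including failures (failures enter as
    0 pA); potency — mean over successes; CV — sample (n-1) SD over all
    trials divided by the mean; PPR — mean second-pulse amplitude over mean
    first-pulse amplitude.
    """
    if len(first_events) < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {len(first_events)}")
    amps = np.array([e.amplitude for e in first_events])
    fails = np.array([e.is_failure for e in first_events])
    successes = amps[~fails]
    amplitude = float(amps.mean())
    failure_rate = float(fails.mean())
    potency = float(successes.mean()) if successes.size else None
    if successes.size == 0:
        cv = None
    elif abs(amplitude) < 1e-12:
        raise ValueError("zero mean amplitude; CV undefined")
    else:
        cv = float(amps.std(ddof=1) / abs(amplitude))
    lats = np.array([e.latency for e in first_events if e.latency is not None])
    lat_mean = float(lats.mean()) if lats.size else None
    lat_sd = float(lats.std(ddof=1)) if lats.size > 1 else None
    ppr = None
    if second_events is not None:
        a2 = np.array([e.amplitude for e in second_events])
        if abs(amplitude) < 1e-12:
            raise ValueError("zero mean first-pulse amplitude; PPR undefined")
        ppr = float(a2.mean() / amplitude)
    return UnitaryEventStats(amplitude=amplitude, potency=potency,
                             failure_rate=failure_rate, cv=cv, ppr=ppr,
                             latency_mean=lat_mean, latency_sd=lat_sd)


def event_kinetics(avg: Sweep, event_onset: float = 0.0):
    """Rise time (20-80% of peak, ms) and decay tau (single-exponential fit
    from peak toward baseline, ms) of an averaged PSC.

    ``avg`` should be an average of >= 5 aligned events, baseline at ~0;
    ``event_onset`` (s) marks where the event search begins.
    """
    dt = avg.dt
    i0 = int(round(event_onset / dt))
    seg = avg.samples[i0:]
    k_pk = int(np.argmax(np.abs(seg)))
    peak = seg[k_pk]
    if abs(peak) < 1e-12:
        raise ValueError("flat trace; no event to measure")
    sign = 1.0 if peak > 0 else -1.0
    mag = sign * seg  # positive-going copy

    def first_crossing(frac):
        level = frac * abs(peak)
        for k in range(k_pk + 1):
            if mag[k] >= level:
                if k == 0:
                    return 0.0
                a, b = mag[k - 1], mag[k]
                return (k - 1 + (level - a) / (b - a)) * dt
        return k_pk * dt

    rise_time = (first_crossing(0.8) - first_crossing(0.2)) * 1e3

    decay = mag[k_pk:]
    n_fit = decay.size
    # fit down to 5% of peak or trace end, whichever first
    below = np.nonzero(decay <= 0.05 * abs(peak))[0]
    if below.size:
        n_fit = max(int(below[0]), 10)
    t = np.arange(n_fit) * dt
    y = decay[:n_fit]

    def model(tt, a, tau):
        return a * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(model, t, y, p0=(abs(peak), max(n_fit * dt / 3, dt)),
                            maxfev=10000)
    except RuntimeError as exc:
        resid = float(np.sqrt(np.mean((y - model(t, abs(peak), n_fit * dt / 3))**2)))
        raise ValueError(
            f"decay fit did not converge (RMS residual of initial guess "
            f"{resid:.3g} pA)") from exc
    return float(rise_time), float(popt[1] * 1e3)


# ---------------------------------------------------------------------------
# conductances / polarity dissociation


def to_conductance(peak: float, v_hold: float, e_rev: float) -> float:
    """Convert a signed peak current (pA) to a conductance (nS):
    g = I / (V_hold - E_rev); requires >= 5 mV of driving force and a
    current whose sign matches the driving force."""
    df = v_hold - e_rev
    if abs(df) < 5.0:
        raise ValueError(f"driving force {df:.1f} mV too small (< 5 mV)")
    g = peak / df
    if g < -1e-12:
        raise ValueError(
            f"current sign ({'inward' if peak < 0 else 'outward'}) is "
            f"inconsistent with the driving force at v_hold={v_hold} mV, "
            f"e_rev={e_rev} mV — mis-assigned component?")
    return max(float(g), 0.0)


def split_components(avg: Sweep, v_hold: float, e_gaba: float, e_glu: float, *,
                     glu_isolated: Optional[Sweep] = None,
                     baseline: float = 10.0, noise_k: float = 3.0):
    """Dissociate GABAergic and glutamatergic conductances by polarity.

    With E_Cl set below the holding potential, GABA_A events are outward
    (positive) and AMPA events inward (negative), so the outward extremum of
    the averaged response gives the GABA conductance and the inward extremum
    the glutamate conductance. If ``glu_isolated`` is supplied (a trace with
    GABA receptors pharmacologically silenced), the glutamate component is
    measured there, and the GABA component from the mixed trace minus the
    isolated one — the fast inward AMPA transient otherwise truncates the
    slower outward GABA peak. Returns
    ``(ConductanceResult GABA, ConductanceResult Glu, ratio G_GABA/G_Glu)``;
    the ratio is None when the glutamate component is absent.

    Component presence is judged on a 0.5 ms boxcar-smoothed copy against
    ``noise_k`` times the smoothed baseline SD (see ``measure_events`` for
    why the raw window extremum would be the wrong statistic).
    """
    if not (e_gaba < v_hold):
        raise ValueError("polarity dissociation requires e_gaba < v_hold")
    if abs(v_hold - e_gaba) < 5.0 or abs(v_hold - e_glu) < 5.0:
        raise ValueError("need >= 5 mV driving force for both components")

    def extrema(samples, dt):
        n_base = max(int(round(baseline * 1e-3 / dt)), 2)
        n_sm = max(int(round(0.5e-3 / dt)), 1)
        sm = np.convolve(samples, np.full(n_sm, 1.0 / n_sm), mode="same")
        y = samples - float(samples[:n_base].mean())
        ys = sm - float(sm[:n_base].mean())
        sd = float(sm[:n_base].std(ddof=1))
        thresh = _detection_threshold(sd, noise_k, samples.size, n_sm)
        return ((float(y.max()), float(ys.max())),
                (float(y.min()), float(ys.min())), thresh)

    if glu_isolated is not None:
        (_, _), (neg, neg_s), th_g = extrema(glu_isolated.samples,
                                             glu_isolated.dt)
        g_glu = to_conductance(neg, v_hold, e_glu) if -neg_s > th_g else 0.0
        gaba_samples = avg.samples - glu_isolated.samples
        (pos, pos_s), (_, _), th = extrema(gaba_samples, avg.dt)
        g_gaba = to_conductance(pos, v_hold, e_gaba) if pos_s > th else 0.0
    else:
        (pos, pos_s), (neg, neg_s), th = extrema(avg.samples, avg.dt)
        g_gaba = to_conductance(pos, v_hold, e_gaba) if pos_s > th else 0.0
        g_glu = to_conductance(neg, v_hold, e_glu) if -neg_s > th else 0.0
    ratio = g_gaba / g_glu if g_glu > 0 else None
    return (ConductanceResult(g=g_gaba, v_hold=v_hold, e_rev=e_gaba, component="GABA"),
            ConductanceResult(g=g_glu, v_hold=v_hold, e_rev=e_glu, component="Glu"),
            ratio)


# ---------------------------------------------------------------------------
# DSI


def dsi(ctl_events: Sequence[EventMeasurement],
        dsi_events: Sequence[EventMeasurement],
        recovery_events: Optional[Sequence[EventMeasurement]] = None,
        min_events: int = 5) -> DSIResult:
    """Depolarization-induced suppression of inhibition.

    Averages event amplitudes (5-10 per condition in the protocol) and
    reports ``suppression = 100 * (1 - dsi/ctl)`` in percent.
    """
    def avg(events, name):
        if len(events) < min_events:
            raise ValueError(f"need >= {min_events} events for {name}")
        return float(np.mean([e.amplitude for e in events]))

    a_ctl = avg(ctl_events, "control")
    a_dsi = avg(dsi_events, "DSI")
    if abs(a_ctl) < 1e-12:
        raise ValueError("control average is zero; suppression undefined")
    a_rec = avg(recovery_events, "recovery") if recovery_events is not None else None
    return DSIResult(ctl_amplitude=a_ctl, dsi_amplitude=a_dsi,
                     recovery_amplitude=a_rec,
                     suppression=100.0 * (1.0 - a_dsi / a_ctl))
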