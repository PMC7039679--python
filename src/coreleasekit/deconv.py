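"""FFT deconvolution of train responses into quantal release rates.

The postsynaptic train current is modelled as the convolution of a quantal
release rate with a stereotyped miniature-PSC kernel (bi-exponential, scaled
to a 20 pA peak). Deconvolution divides the trace spectrum point-by-point by
the kernel spectrum and inverse-transforms; the trace is smoothed first with
repeated 3-point binomial passes, and a relative magnitude floor on the
kernel spectrum regularizes the near-zero high-frequency bins a discretized
kernel inevitably has (the floor at its default 1e-3 leaves the passband
untouched; setting it to 0 reproduces raw division).

Rates are expressed in quanta/s, one quantum being one kernel's worth of
charge: deconvolving the kernel itself yields a unit-area impulse.

Synchronous release per pulse is the release-rate area in the 5 ms bin after
the pulse onset; asynchronous release is the area in the 15 ms bin before
the next onset (a virtual onset one period after the last pulse closes the
train); their ratio is the per-pulse synchronicity ratio (SR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .trace_io import Sweep

__all__ = [
    "Kernel",
    "ReleaseRateHistogram",
    "make_kernel",
    "binomial_smooth",
    "release_rate",
    "synchronicity",
    "deconvolve_train",
]

KERNEL_PEAK_PA = 20.0
SYNC_BIN_S = 0.005
ASYNC_BIN_S = 0.015
ASYNC_FLOOR_QUANTA = 1e-3


@dataclass(frozen=True)
class Kernel:
    """Artificial miniature PSC used as the deconvolution template."""

    samples: np.ndarray      # pA, peak exactly 20
    dt: float                # s
    rise_time: float         # ms
    decay_tau: float         # ms

    @property
    def charge(self) -> float:
        """Integral of the kernel, pA*s (defines one quantum)."""
        return float(self.samples.sum() * self.dt)


@dataclass
class ReleaseRateHistogram:
    rate: np.ndarray                 # quanta/s
    dt: float
    sync_auc: Optional[np.ndarray] = None    # quanta, per pulse
    async_auc: Optional[np.ndarray] = None   # quanta, per pulse
    sr: Optional[np.ndarray] = None          # sync/async; NaN = undefined
    meta: dict = field(default_factory=dict)

    @property
    def total_quanta(self) -> float:
        return float(self.rate.sum() * self.dt)


def make_kernel(rise_time: float, decay_tau: float, dt: float = 5e-5,
                length: float = None) -> Kernel:
    """Bi-exponential kernel with its peak scaled to exactly 20 pA.

    ``rise_time`` and ``decay_tau`` in ms (rise must be faster than decay);
    ``length`` in ms defaults to, and must be at least, 5 decay taus so the
    tail has decayed below 1% of the peak.
    """
    if rise_time >= decay_tau:
        raise ValueError("rise_time must be smaller than decay_tau "
                         "(degenerate kernel shape)")
    if length is None:
        length = 8.0 * decay_tau
    if length < 5.0 * decay_tau:
        raise ValueError("kernel length must be >= 5 decay taus")
    n = int(round(length * 1e-3 / dt))
    t = np.arange(n) * dt
    tr, td = rise_time * 1e-3, decay_tau * 1e-3
    shape = np.exp(-t / td) - np.exp(-t / tr)
    samples = shape * (KERNEL_PEAK_PA / shape.max())
    samples[int(np.argmax(samples))] = KERNEL_PEAK_PA  # exact, not 20*(1-ulp)
    return Kernel(samples=samples, dt=dt, rise_time=rise_time,
                  decay_tau=decay_tau)


def binomial_smooth(trace: np.ndarray, repetitions: int = 50) -> np.ndarray:
    """Apply the (1/4, 1/2, 1/4) binomial kernel ``repetitions`` times with
    edge replication. 50 passes approximate a Gaussian of SD = 5 samples."""
    if repetitions < 0:
        raise ValueError("repetitions must be >= 0")
    y = np.asarray(trace, float).copy()
    for _ in range(repetitions):
        padded = np.concatenate([y[:1], y, y[-1:]])
        y = 0.25 * padded[:-2] + 0.5 * padded[1:-1] + 0.25 * padded[2:]
    return y


def release_rate(trace: np.ndarray, kernel: Kernel, dt: float = None,
                 eps: float = 1e-3) -> ReleaseRateHistogram:
    """Deconvolve a baseline-subtracted (and pre-smoothed) trace by the
    kernel, returning the quantal release rate.

    Both signals are zero-padded to a power of two at least the sum of
    their lengths (preventing circular wraparound); the spectral division
    clamps kernel-spectrum magnitudes below ``eps`` times the spectral
    maximum (phase preserved). The impulse response is converted to
    quanta/s by dividing by ``dt``.
    """
    if isinstance(trace, Sweep):
        dt = trace.dt
        trace = trace.samples
    if dt is None:
        dt = kernel.dt
    if not math.isclose(dt, kernel.dt, rel_tol=1e-9):
        raise ValueError("trace and kernel must share the sampling interval")
    trace = np.asarray(trace, float)
    n = int(2 ** math.ceil(math.log2(max(trace.size + kernel.samples.size, 2))))
    ft = np.fft.rfft(trace, n)
    fk = np.fft.rfft(kernel.samples, n)
    mag = np.abs(fk)
    floor = eps * mag.max()
    if mag.max() == 0:
        raise ValueError("kernel spectrum is identically zero")
    if eps > 0:
        low = mag < floor
        # clamp magnitude, keep phase; bins with zero magnitude get the floor
        fk = np.where(low, np.where(mag > 0, fk * (floor / np.maximum(mag, 1e-300)),
                                    floor), fk)
        if np.all(low):
            raise ValueError("kernel spectrum entirely below the floor")
    rate = np.fft.irfft(ft / fk, n)[:trace.size] / dt
    return ReleaseRateHistogram(rate=rate, dt=dt,
                                meta={"eps": eps, "n_fft": n,
                                      "kernel_charge_pa_s": kernel.charge})


def synchronicity(hist: ReleaseRateHistogram, step_onsets: Sequence[float], *,
                  period: float = None, sync_bin: float = SYNC_BIN_S,
                  async_bin: float = ASYNC_BIN_S,
                  floor: float = ASYNC_FLOOR_QUANTA) -> ReleaseRateHistogram:
    """Per-pulse synchronous/asynchronous AUCs and synchronicity ratios.

    For pulse i: sync = area of the rate over [onset_i, onset_i + 5 ms];
    async = area over [onset_{i+1} - 15 ms, onset_{i+1}], the final pulse
    using a virtual next onset one period later. SR_i = sync/async, NaN
    (undefined) when the async area is below ``floor`` quanta. Fills the
    histogram's per-pulse fields in place and returns it.
    """
    onsets = np.asarray(step_onsets, float)
    if onsets.size == 0:
        raise ValueError("no step onsets supplied")
    if period is None:
        period = float(np.median(np.diff(onsets))) if onsets.size > 1 else 0.02
    if async_bin > period + 1e-12:
        raise ValueError("async bin longer than the inter-pulse period")
    dt = hist.dt

    def area(t0, t1):
        i0 = max(int(round(t0 / dt)), 0)
        i1 = min(int(round(t1 / dt)), hist.rate.size)
        return float(hist.rate[i0:i1].sum() * dt)

    sync = np.empty(onsets.size)
    asyn = np.empty(onsets.size)
    for i, on in enumerate(onsets):
        nxt = onsets[i + 1] if i + 1 < onsets.size else on + period
        sync[i] = area(on, on + sync_bin)
        asyn[i] = area(nxt - async_bin, nxt)
    sr = np.where(asyn > floor, sync / np.where(asyn > floor, asyn, 1.0), np.nan)
    hist.sync_auc, hist.async_auc, hist.sr = sync, asyn, sr
    return hist


def deconvolve_train(sweep: Sweep, kernel: Kernel, *,
                     smooth_repetitions: int = 50, eps: float = 1e-3,
                     baseline: float = 0.01,
                     polarity: str = "auto") -> ReleaseRateHistogram:
    """Full per-sweep protocol: baseline-subtract, binomial-smooth,
    deconvolve, and (when the sweep carries pulse times) compute per-pulse
    AUCs and synchronicity ratios.

    The kernel peak is positive by construction, so the trace polarity must
    match: ``polarity="auto"`` flips inward-going (negative) event trains so
    release rates come out positive; "inward"/"outward" force the choice.
    """
    n_base = max(int(round(baseline / sweep.dt)), 1)
    y = sweep.samples - sweep.samples[:n_base].mean()
    y = binomial_smooth(y, smooth_repetitions)
    if polarity == "auto":
        polarity = "inward" if -y.min() > y.max() else "outward"
    if polarity == "inward":
        y = -y
    elif polarity != "outward":
        raise ValueError("polarity must be 'auto', 'inward' or 'outward'")
    hist = release_rate(y, kernel, dt=sweep.dt, eps=eps)
    if sweep.stim is not None and sweep.stim.pulse_times:
        period = (1.0 / sweep.stim.pulse_rate
                  if sweep.stim.pulse_rate else None)
        synchronicity(hist, sweep.stim.pulse_times, period=period)
    return hist
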