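"""Sweep/recording data model and the native columnar text interchange format.

Unit conventions (enforced here, assumed everywhere downstream):

* time is always seconds; kinetic parameters exposed to users in ms are
  converted at function boundaries, never stored;
* current-clamp and field samples are mV, voltage-clamp samples are pA;
* inward currents are negative, outward currents positive.

The native format is a plain-text file: a file-level ``key: value`` header
(solutions and temperature as JSON values), then one block per sweep, each
with its own ``key: value`` header followed by one column of samples printed
with 17 significant digits so float64 round-trips exactly.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Sweep",
    "StepProtocol",
    "CellRecording",
    "read_recording",
    "write_recording",
    "FormatError",
]

CLAMP_MODES = ("current_clamp", "voltage_clamp", "field")
#: physical unit of the sample array per clamp mode
UNITS = {"current_clamp": "mV", "voltage_clamp": "pA", "field": "mV"}

MAGIC = "# coreleasekit native v1"


class FormatError(ValueError):
    """Raised when a native file violates the format contract."""


@dataclass(frozen=True)
class StepProtocol:
    """Stimulus metadata for a sweep.

    Parameters
    ----------
    onset, duration : float
        Step onset and duration in seconds.
    amplitude : float
        Step amplitude — pA in current clamp, mV in voltage clamp.
    pulse_times : tuple of float, optional
        Onsets (s) of presynaptic action potentials / light pulses driving
        evoked responses; strictly increasing.
    pulse_rate : float, optional
        Nominal pulse rate in Hz (e.g. 50 for the 25-pulse trains).
    """

    onset: float = 0.0
    duration: float = 0.0
    amplitude: float = 0.0
    pulse_times: Optional[tuple] = None
    pulse_rate: Optional[float] = None

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError(f"step onset must be >= 0, got {self.onset}")
        if self.duration < 0:
            raise ValueError("step duration must be >= 0")
        if self.pulse_times is not None:
            pt = tuple(float(t) for t in self.pulse_times)
            if any(b <= a for a, b in zip(pt, pt[1:])):
                raise ValueError("pulse_times must be strictly increasing")
            object.__setattr__(self, "pulse_times", pt)


@dataclass
class Sweep:
    """One uniformly sampled trace.

    ``samples`` holds mV (current clamp, field) or pA (voltage clamp);
    ``dt`` is the sampling interval in seconds; ``holding`` is the holding
    potential (mV, voltage clamp) or bias current (pA, current clamp).
    """

    samples: np.ndarray
    dt: float
    clamp_mode: str
    holding: float = 0.0
    stim: Optional[StepProtocol] = None
    sweep_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.dt > 0):
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.clamp_mode not in CLAMP_MODES:
            raise ValueError(
                f"clamp_mode must be one of {CLAMP_MODES}, got {self.clamp_mode!r}"
            )
        if self.stim is not None and self.stim.duration > 0:
            if self.stim.onset + self.stim.duration > self.duration + self.dt / 2:
                raise ValueError("stimulus extends past the end of the sweep")

    @property
    def units(self) -> str:
        return UNITS[self.clamp_mode]

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Sweep length in seconds (= n_samples * dt)."""
        return self.samples.size * self.dt

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds (first sample at t = 0)."""
        return np.arange(self.samples.size) * self.dt

    def copy(self) -> "Sweep":
        return replace(self, samples=self.samples.copy())


@dataclass
class CellRecording:
    """An ordered collection of sweeps from one cell plus recording context.

    ``internal_solution`` / ``external_solution`` map salt names (e.g.
    ``"KCl"``, ``"MgCl2"``) to concentrations in mM; they feed the Nernst
    calculation in :mod:`coreleasekit.synaptic`.
    """

    sweeps: list = field(default_factory=list)
    internal_solution: dict = field(default_factory=dict)
    external_solution: dict = field(default_factory=dict)
    temperature: float = 33.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (20.0 <= self.temperature <= 40.0):
            raise ValueError(
                f"temperature {self.temperature} degC outside the 20-40 degC "
                "recording range"
            )
        for name, sol in (("internal", self.internal_solution),
                          ("external", self.external_solution)):
            for salt, conc in sol.items():
                if conc < 0:
                    raise ValueError(f"{name} [{salt}] = {conc} mM is negative")

    def __len__(self):
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)


# ---------------------------------------------------------------------------
# native format


def _fmt(x: float) -> str:
    return f"{float(x):.17g}"


def _stim_to_json(stim: Optional[StepProtocol]) -> str:
    if stim is None:
        return "null"
    d = {
        "onset": stim.onset,
        "duration": stim.duration,
        "amplitude": stim.amplitude,
        "pulse_times": list(stim.pulse_times) if stim.pulse_times else None,
        "pulse_rate": stim.pulse_rate,
    }
    return json.dumps(d)


def _stim_from_json(s: str) -> Optional[StepProtocol]:
    d = json.loads(s)
    if d is None:
        return None
    return StepProtocol(
        onset=d["onset"],
        duration=d["duration"],
        amplitude=d["amplitude"],
        pulse_times=tuple(d["pulse_times"]) if d.get("pulse_times") else None,
        pulse_rate=d.get("pulse_rate"),
    )


def write_recording(rec: CellRecording, path) -> None:
    """Serialize ``rec`` to the native text format at ``path``.

    Numeric fields are written with 17 significant digits so that
    read(write(rec)) reproduces samples bit-for-bit.
    """
    if len(rec.sweeps) == 0:
        raise ValueError("recording has no sweeps; nothing to write")
    buf = io.StringIO()
    buf.write(MAGIC + "\n")
    buf.write(f"temperature_c: {_fmt(rec.temperature)}\n")
    buf.write(f"internal_solution: {json.dumps(rec.internal_solution)}\n")
    buf.write(f"external_solution: {json.dumps(rec.external_solution)}\n")
    buf.write(f"metadata: {json.dumps(rec.metadata)}\n")
    buf.write(f"n_sweeps: {len(rec.sweeps)}\n")
    for i, sw in enumerate(rec.sweeps):
        buf.write(f"sweep: {sw.sweep_id or i}\n")
        buf.write(f"clamp_mode: {sw.clamp_mode}\n")
        buf.write(f"units: {sw.units}\n")
        buf.write(f"dt: {_fmt(sw.dt)}\n")
        buf.write(f"holding: {_fmt(sw.holding)}\n")
        buf.write(f"stim: {_stim_to_json(sw.stim)}\n")
        buf.write(f"n_samples: {sw.n_samples}\n")
        buf.write("\n".join(_fmt(v) for v in sw.samples))
        buf.write("\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _read_native(path) -> CellRecording:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != MAGIC:
        raise FormatError(f"{path}: missing native-format magic line")
    pos = 1

    def header_line(expect: str) -> str:
        nonlocal pos
        if pos >= len(lines):
            raise FormatError(f"{path}: truncated file, expected '{expect}:'")
        line = lines[pos]
        pos += 1
        key, _, val = line.partition(":")
        if key.strip() != expect:
            raise FormatError(
                f"{path}: expected header field '{expect}', found {key.strip()!r}"
            )
        return val.strip()

    temperature = float(header_line("temperature_c"))
    internal = json.loads(header_line("internal_solution"))
    external = json.loads(header_line("external_solution"))
    metadata = json.loads(header_line("metadata"))
    n_sweeps = int(header_line("n_sweeps"))

    sweeps = []
    for _ in range(n_sweeps):
        sweep_id = header_line("sweep")
        clamp_mode = header_line("clamp_mode")
        if clamp_mode not in CLAMP_MODES:
            raise FormatError(f"{path}: unknown clamp_mode {clamp_mode!r}")
        units = header_line("units")
        if units != UNITS[clamp_mode]:
            raise FormatError(
                f"{path}: units {units!r} inconsistent with clamp_mode "
                f"{clamp_mode!r} (expected {UNITS[clamp_mode]!r})"
            )
        dt = float(header_line("dt"))
        if not (dt > 0) or not math.isfinite(dt):
            raise FormatError(f"{path}: invalid dt {dt}")
        holding = float(header_line("holding"))
        stim = _stim_from_json(header_line("stim"))
        n = int(header_line("n_samples"))
        if pos + n > len(lines):
            raise FormatError(f"{path}: sweep {sweep_id!r} truncated")
        samples = np.array([float(v) for v in lines[pos:pos + n]])
        pos += n
        sweeps.append(
            Sweep(samples=samples, dt=dt, clamp_mode=clamp_mode,
                  holding=holding, stim=stim, sweep_id=sweep_id)
        )
    return CellRecording(
        sweeps=sweeps, internal_solution=internal, external_solution=external,
        temperature=temperature, metadata=metadata,
    )


def _read_abf(path) -> CellRecording:
    try:
        import pyabf  # type: ignore
    except ImportError as exc:  # pragma: no cover - depends on install
        raise ImportError(
            "ABF import requires the optional 'pyabf' package"
        ) from exc
    abf = pyabf.ABF(str(path))  # pragma: no cover
    sweeps = []
    mode = "voltage_clamp" if "Clamp" in (abf.adcUnits[0] or "") else "current_clamp"
    for i in abf.sweepList:
        abf.setSweep(i)
        sweeps.append(Sweep(samples=np.asarray(abf.sweepY, float),
                            dt=1.0 / abf.dataRate, clamp_mode=mode,
                            sweep_id=str(i)))
    return CellRecording(sweeps=sweeps, metadata={"source": str(path)})


def _read_nwb(path) -> CellRecording:
    try:
        import pynwb  # type: ignore  # noqa: F401
    except ImportError as exc:  # pragma: no cover - depends on install
        raise ImportError(
            "NWB import requires the optional 'pynwb' package"
        ) from exc
    raise NotImplementedError(  # pragma: no cover
        "NWB mapping is only available when pynwb is installed"
    )


def read_recording(path, format: str = "native") -> CellRecording:
    """Read a recording.

    Parameters
    ----------
    path : path-like
    format : {"native", "abf", "nwb"}
        ``native`` is the package's text format; ``abf``/``nwb`` delegate to
        the optional pyabf/pynwb readers and only map their content onto
        :class:`Sweep`.
    """
    readers = {"native": _read_native, "abf": _read_abf, "nwb": _read_nwb}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    return readers[format](path)
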