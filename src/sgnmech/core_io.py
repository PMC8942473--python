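"""Domain containers and plain-text readers/writers.

Canonical internal units
------------------------
time ms, voltage mV, current pA, conductance nS, displacement um,
concentration uM, phases in radians on [0, 2*pi).  The CLI accepts nA for
injected current and converts on the way in.

File formats are deliberately plain: traces are one sample per line below a
``# key=value`` header, spike trains are one time (ms) per line, and result
records are ``key = value`` text that round-trips field-for-field.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "FormatError", "Trace", "SinusoidStimulus", "StepRampStimulus",
    "SpikeTrain", "AnalysisConfig", "read_trace", "write_trace",
    "read_spike_times", "write_spike_times", "read_results", "write_results",
    "register_result", "TWO_PI",
]

TWO_PI = 2.0 * math.pi

#: kind -> required units
KIND_UNITS = {"voltage": "mV", "current": "pA", "displacement": "um"}
_UNIT_ALIASES = {"μm": "um", "µm": "um", "micron": "um", "mv": "mV", "pa": "pA"}


class FormatError(ValueError):
    """Raised for malformed headers, bodies, or inconsistent metadata."""


def normalize_units(units: str) -> str:
    return _UNIT_ALIASES.get(units, units)


@dataclass
class Trace:
    """A uniformly sampled voltage, current or displacement record.

    Parameters
    ----------
    dt : sampling interval in ms (> 0)
    samples : the sample values, one per time point
    kind : one of ``voltage``, ``current``, ``displacement``
    units : must match the kind (mV, pA, um respectively)
    t0 : time of the first sample, ms
    """

    dt: float
    samples: np.ndarray
    kind: str
    units: str = ""
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise FormatError("trace requires a non-empty 1-d sample array")
        if not self.dt > 0:
            raise FormatError(f"dt must be positive, got {self.dt}")
        if self.kind not in KIND_UNITS:
            raise FormatError(f"unknown trace kind {self.kind!r}")
        if not self.units:
            self.units = KIND_UNITS[self.kind]
        self.units = normalize_units(self.units)
        if self.units != KIND_UNITS[self.kind]:
            raise FormatError(
                f"units {self.units!r} inconsistent with kind {self.kind!r} "
                f"(expected {KIND_UNITS[self.kind]!r})")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in ms (n * dt)."""
        return self.n * self.dt

    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.n)


@dataclass
class SinusoidStimulus:
    """Sinusoidal current injection or mechanical displacement.

    ``value(t)`` is amplitude * sin(2*pi*f*(t-onset)/1000 + phase_offset)
    inside [onset, onset+duration) and 0 elsewhere.  Spike phase relative to
    this stimulus is 2*pi*f*(t-onset) mod 2*pi (the phase_offset shifts the
    waveform, not the phase reference).
    """

    modality: str              # "current" (amplitude pA) or "displacement" (um)
    frequency: float           # Hz
    amplitude: float           # pA or um
    phase_offset: float = 0.0  # radians
    onset: float = 0.0         # ms
    duration: float = 1000.0   # ms

    def __post_init__(self):
        if self.modality not in ("current", "displacement"):
            raise FormatError(f"unknown stimulus modality {self.modality!r}")
        if not self.frequency > 0:
            raise FormatError("frequency must be positive")
        if self.amplitude < 0:
            raise FormatError("amplitude must be non-negative")
        if not self.duration > 0:
            raise FormatError("duration must be positive")

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        active = (t >= self.onset) & (t < self.onset + self.duration)
        phase = TWO_PI * self.frequency * (t - self.onset) / 1000.0
        return np.where(active,
                        self.amplitude * np.sin(phase + self.phase_offset),
                        0.0)


@dataclass
class StepRampStimulus:
    """Rectangular step or ramp-and-hold stimulus.

    slew_rate is in um/ms (or pA/ms for current); 0 means an instantaneous
    step to ``amplitude``.
    """

    modality: str
    amplitude: float
    onset: float = 0.0
    duration: float = 100.0
    slew_rate: float = 0.0

    def __post_init__(self):
        if self.modality not in ("current", "displacement"):
            raise FormatError(f"unknown stimulus modality {self.modality!r}")
        if self.amplitude < 0:
            raise FormatError("amplitude must be non-negative")
        if self.slew_rate < 0:
            raise FormatError("slew_rate must be non-negative")

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        active = (t >= self.onset) & (t < self.onset + self.duration)
        if self.slew_rate == 0:
            level = np.full_like(t, self.amplitude)
        else:
            level = np.minimum(self.amplitude,
                               self.slew_rate * (t - self.onset))
        return np.where(active, level, 0.0)


Stimulus = Union[SinusoidStimulus, StepRampStimulus]


@dataclass
class SpikeTrain:
    """Event times (ms, strictly increasing) bound to an optional stimulus."""

    times: np.ndarray
    record_duration: float
    stimulus: Optional[Stimulus] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise FormatError("spike times must be a 1-d sequence")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise FormatError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] > self.record_duration:
                raise FormatError(
                    "spike times must lie within [0, record_duration]")
        if not self.record_duration > 0:
            raise FormatError("record_duration must be positive")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class AnalysisConfig:
    """Analysis-wide settings.

    spike_criterion : mV; amplitude a valid action potential must exceed
    dead_time : ms; events closer than this are merged by spike detection
    n_bins : cycle-histogram bin count (>= 8; default 10 degree bins)
    min_spikes_for_vs : minimum spike count for a valid vector strength
    temperature : kelvin, used to convert Boltzmann slope to gating force
    permutations : shuffles used for polar resultant significance
    """

    spike_criterion: float = 0.0
    dead_time: float = 1.0
    n_bins: int = 36
    min_spikes_for_vs: int = 5
    temperature: float = 295.0
    rng_seed: int = 0
    permutations: int = 10000

    def __post_init__(self):
        if self.n_bins < 8:
            raise FormatError("n_bins must be >= 8")
        if self.min_spikes_for_vs < 2:
            raise FormatError("min_spikes_for_vs must be >= 2")
        if not self.temperature > 0:
            raise FormatError("temperature must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# trace files

def _fmt(x: float) -> str:
    # repr() of a Python float is the shortest string that round-trips
    return repr(float(x))


def write_trace(trace: Trace, path) -> None:
    lines = ["# sgnmech-trace v1",
             f"# dt={_fmt(trace.dt)}",
             f"# t0={_fmt(trace.t0)}",
             f"# kind={trace.kind}",
             f"# units={trace.units}"]
    lines.extend(_fmt(s) for s in trace.samples)
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_header(lines) -> dict:
    header = {}
    for raw in lines:
        body = raw[1:].strip()
        if "=" not in body:
            continue
        key, _, value = body.partition("=")
        key, value = key.strip(), value.strip()
        if key in header and header[key] != value:
            raise FormatError(f"contradictory header values for {key!r}")
        header[key] = value
    return header


def read_trace(path) -> Trace:
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    header_lines = [ln for ln in raw_lines if ln.startswith("#")]
    header = _parse_header(header_lines)
    for key in ("dt", "kind", "units"):
        if key not in header:
            raise FormatError(f"{path}: missing required header key {key!r}")
    samples = []
    for i, ln in enumerate(raw_lines, start=1):
        if ln.startswith("#") or not ln.strip():
            continue
        try:
            samples.append(float(ln))
        except ValueError:
            raise FormatError(f"{path}: non-numeric sample on line {i}: {ln!r}")
    if not samples:
        raise FormatError(f"{path}: no samples")
    return Trace(dt=float(header["dt"]), samples=np.array(samples),
                 kind=header["kind"], units=header["units"],
                 t0=float(header.get("t0", 0.0)))


# ---------------------------------------------------------------------------
# spike-time files

def write_spike_times(train: SpikeTrain, path) -> None:
    lines = [f"# record_duration={_fmt(train.record_duration)}"]
    lines.extend(_fmt(t) for t in train.times)
    Path(path).write_text("\n".join(lines) + "\n")


def read_spike_times(path) -> SpikeTrain:
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    header = _parse_header([ln for ln in raw_lines if ln.startswith("#")])
    times = []
    for i, ln in enumerate(raw_lines, start=1):
        if ln.startswith("#") or not ln.strip():
            continue
        try:
            times.append(float(ln))
        except ValueError:
            raise FormatError(f"{path}: non-numeric time on line {i}: {ln!r}")
    if "record_duration" in header:
        duration = float(header["record_duration"])
    elif times:
        duration = times[-1]
    else:
        raise FormatError(f"{path}: empty spike file with no record_duration")
    return SpikeTrain(times=np.array(times), record_duration=duration)


# ---------------------------------------------------------------------------
# structured result records

_RESULT_REGISTRY: dict = {}


def register_result(cls):
    """Class decorator: make a dataclass writable by :func:`write_results`."""
    _RESULT_REGISTRY[cls.__name__] = cls
    return cls


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, tuple):
        return list(value)
    return value


def write_results(record, path) -> None:
    """Write a registered result dataclass as ``key = value`` text."""
    name = type(record).__name__
    if name not in _RESULT_REGISTRY or not dataclasses.is_dataclass(record):
        raise TypeError(f"unknown result record type {name!r}")
    lines = [f"type = {name}"]
    for f in dataclasses.fields(record):
        value = _jsonable(getattr(record, f.name))
        lines.append(f"{f.name} = {json.dumps(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path):
    """Read a record written by :func:`write_results` back field-for-field."""
    # ensure all result classes have registered themselves
    from . import fits, phaselock  # noqa: F401
    path = Path(path)
    fields = {}
    type_name = None
    for i, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        key, sep, value = ln.partition("=")
        if not sep:
            raise FormatError(f"{path}: malformed line {i}: {ln!r}")
        key, value = key.strip(), value.strip()
        if key == "type":
            type_name = value
        else:
            fields[key] = json.loads(value)
    if type_name is None:
        raise FormatError(f"{path}: missing 'type' line")
    cls = _RESULT_REGISTRY.get(type_name)
    if cls is None:
        raise FormatError(f"{path}: unknown result type {type_name!r}")
    return cls(**fields)
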