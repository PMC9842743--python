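"""Voltage pulse/protocol data model, protocol builders and trace I/O.

All quantities are SI (seconds, volts, amperes).  Traces are exchanged as
plain CSV files (``time_s,current_A`` header, full ``repr`` precision) with
an optional JSON metadata side-car so a round trip is lossless.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from molsynapse.errors import InvalidProtocolError, TraceParseError

PULSE_SHAPES = ("square", "triangle")

#: default number of voltage samples per pulse used by the protocol builders
SAMPLES_PER_PULSE = 100


@dataclass(frozen=True)
class VoltagePulse:
    """One voltage pulse: shape, signed amplitude, width and trailing gap."""

    shape: str
    amplitude: float
    width: float
    interval_after: float = 0.0

    def __post_init__(self):
        if self.shape not in PULSE_SHAPES:
            raise InvalidProtocolError(
                f"unknown pulse shape {self.shape!r}; expected one of {PULSE_SHAPES}"
            )
        if not (self.width > 0) or not math.isfinite(self.width):
            raise InvalidProtocolError(f"pulse width must be > 0, got {self.width}")
        if self.interval_after < 0 or not math.isfinite(self.interval_after):
            raise InvalidProtocolError(
                f"pulse interval_after must be >= 0, got {self.interval_after}"
            )

    @property
    def duration(self) -> float:
        return self.width + self.interval_after

    def value_at(self, u: float) -> float:
        """Voltage at fractional position ``u`` in [0, 1) within the pulse width."""
        if self.shape == "square":
            return self.amplitude
        # triangle: linear ramp 0 -> amplitude -> 0
        return self.amplitude * (1.0 - abs(2.0 * u - 1.0))


@dataclass
class VoltageProtocol:
    """An ordered pulse sequence plus read bias and sampling rate.

    Time origin is 0 at the rising edge of the first pulse; between pulses
    (during ``interval_after``) the device sits at ``read_voltage``.
    """

    pulses: list[VoltagePulse]
    read_voltage: float = 0.0
    sample_rate: float = 100.0

    def __post_init__(self):
        if not self.pulses:
            raise InvalidProtocolError("protocol must contain at least one pulse")
        if not (self.sample_rate > 0):
            raise InvalidProtocolError(
                f"sample_rate must be > 0, got {self.sample_rate}"
            )

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.pulses)

    def pulse_windows(self) -> list[tuple[float, float]]:
        """Per-pulse ``(t_start, t_end)`` of the active pulse width."""
        out, t = [], 0.0
        for p in self.pulses:
            out.append((t, t + p.width))
            t += p.duration
        return out

    def sample(self) -> tuple[np.ndarray, np.ndarray]:
        """Discretize the drive waveform at ``sample_rate``.

        Returns ``(t, v)`` with ``t`` uniform on ``[0, total_duration)``.
        """
        dt = 1.0 / self.sample_rate
        n = max(1, int(round(self.total_duration / dt)))
        t = np.arange(n) * dt
        v = np.full(n, self.read_voltage, dtype=float)
        start = 0.0
        for p in self.pulses:
            i0 = int(np.ceil(start / dt - 1e-9))
            i1 = int(np.ceil((start + p.width) / dt - 1e-9))
            i1 = min(i1, n)
            if i1 > i0:
                u = (t[i0:i1] - start) / p.width
                if p.shape == "square":
                    v[i0:i1] = p.amplitude
                else:
                    v[i0:i1] = p.amplitude * (1.0 - np.abs(2.0 * u - 1.0))
            start += p.duration
        return t, v

    def to_dict(self) -> dict:
        return {
            "read_voltage": self.read_voltage,
            "sample_rate": self.sample_rate,
            "pulses": [
                {
                    "shape": p.shape,
                    "amplitude": p.amplitude,
                    "width": p.width,
                    "interval_after": p.interval_after,
                }
                for p in self.pulses
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        try:
            pulses = [VoltagePulse(**p) for p in d["pulses"]]
        except (KeyError, TypeError) as exc:
            raise InvalidProtocolError(f"malformed protocol mapping: {exc}") from exc
        return cls(
            pulses=pulses,
            read_voltage=float(d.get("read_voltage", 0.0)),
            sample_rate=float(d.get("sample_rate", 100.0)),
        )


@dataclass
class CurrentTrace:
    """Time-stamped current samples with free-form provenance metadata."""

    time: np.ndarray
    current: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.ndim != 1 or self.current.ndim != 1:
            raise TraceParseError("time and current must be 1-D arrays")
        if self.time.size != self.current.size:
            raise TraceParseError(
                f"time ({self.time.size}) and current ({self.current.size}) "
                "must have equal length"
            )
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise TraceParseError("time must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CurrentTrace):
            return NotImplemented
        return (
            np.array_equal(self.time, other.time)
            and np.array_equal(self.current, other.current)
            and self.meta == other.meta
        )


def build_pulse_train(
    n: int,
    amplitude: float,
    width: float,
    interval: float = 0.0,
    shape: str = "square",
    read_voltage: float = 0.0,
    sample_rate: float | None = None,
) -> VoltageProtocol:
    """``n`` identical pulses in order; e.g. the 75-pulse triangle trains."""
    if n < 1:
        raise InvalidProtocolError(f"pulse count must be >= 1, got {n}")
    pulse = VoltagePulse(shape, amplitude, width, interval)
    if sample_rate is None:
        sample_rate = SAMPLES_PER_PULSE / width
    return VoltageProtocol([pulse] * n, read_voltage=read_voltage, sample_rate=sample_rate)


def build_pulse_pair(
    amplitude: float,
    width: float,
    interval: float,
    shape: str = "square",
    read_voltage: float = 0.0,
    sample_rate: float | None = None,
) -> VoltageProtocol:
    """Two identical pulses separated by ``interval`` (paired-pulse drive)."""
    if sample_rate is None:
        sample_rate = SAMPLES_PER_PULSE / width
    pulses = [
        VoltagePulse(shape, amplitude, width, interval),
        VoltagePulse(shape, amplitude, width, 0.0),
    ]
    return VoltageProtocol(pulses, read_voltage=read_voltage, sample_rate=sample_rate)


#: (amplitude, width) of the endurance write and read pulses
WRITE_PULSE = (-1.0, 1.0)
READ_PULSE = (-0.25, 10.0)


def build_write_read_cycle(
    n_cycles: int,
    write: tuple[float, float] = WRITE_PULSE,
    read: tuple[float, float] = READ_PULSE,
    sample_rate: float | None = None,
) -> VoltageProtocol:
    """Alternating write (-1.0 V, 1 s) and read (-0.25 V, 10 s) square pulses."""
    if n_cycles < 1:
        raise InvalidProtocolError(f"n_cycles must be >= 1, got {n_cycles}")
    w_amp, w_width = write
    r_amp, r_width = read
    if sample_rate is None:
        sample_rate = SAMPLES_PER_PULSE / min(w_width, r_width)
    pulses = []
    for _ in range(n_cycles):
        pulses.append(VoltagePulse("square", w_amp, w_width, 0.0))
        pulses.append(VoltagePulse("square", r_amp, r_width, 0.0))
    return VoltageProtocol(pulses, read_voltage=0.0, sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# Trace I/O: CSV data + JSON metadata side-car
# ---------------------------------------------------------------------------

_HEADER = ["time_s", "current_A"]


def _sidecar_path(destination: Path) -> Path:
    return destination.with_name(destination.name + ".meta.json")


def write_trace(trace: CurrentTrace, destination) -> Path:
    """Write ``trace`` to CSV (plus JSON side-car when metadata is present).

    Numbers are written with ``repr`` so a read round trip is bit-exact.
    """
    destination = Path(destination)
    with destination.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for t, i in zip(trace.time, trace.current):
            writer.writerow([repr(float(t)), repr(float(i))])
    if trace.meta:
        with _sidecar_path(destination).open("w") as fh:
            json.dump(trace.meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return destination


def read_trace(source) -> CurrentTrace:
    """Read a CSV trace written by :func:`write_trace`."""
    source = Path(source)
    times, currents = [], []
    with source.open("r", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise TraceParseError(f"{source}: empty file")
        if [h.strip() for h in header] != _HEADER:
            raise TraceParseError(
                f"{source}: line 1: expected header {','.join(_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise TraceParseError(
                    f"{source}: line {lineno}: expected 2 fields, got {len(row)}"
                )
            try:
                times.append(float(row[0]))
                currents.append(float(row[1]))
            except ValueError as exc:
                raise TraceParseError(f"{source}: line {lineno}: {exc}") from exc
    meta = {}
    sidecar = _sidecar_path(source)
    if sidecar.exists():
        with sidecar.open("r") as fh:
            meta = json.load(fh)
    return CurrentTrace(np.array(times), np.array(currents), meta)
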