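"""Pen-trace data model and plain-text CSV I/O.

A trace is an ordered sequence of time-stamped stylus samples: time in ms
since the trace start, pen-tip position in mm, and pen pressure in raw
device units (0 means the pen is off the surface; the device maximum is
carried as metadata, default 1023).  Pen lifts are recorded as pressure-0
samples rather than gaps, so the pressure channel keeps the sudden changes
that the dexterity variables measure.

The on-disk format is a UTF-8, LF-terminated CSV with leading ``# key=value``
metadata lines (sorted by key) and the fixed header ``t_ms,x_mm,y_mm,pressure``.
Numbers are written with ``repr``-faithful precision so write -> read is the
identity and writing is byte-deterministic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "PenSample",
    "Trace",
    "TraceFormatError",
    "TraceValidationError",
    "read_trace_csv",
    "write_trace_csv",
    "validate_trace",
]

_HEADER = "t_ms,x_mm,y_mm,pressure"
_GROUPS = ("patient", "control", "unknown")
_HANDS = ("dominant", "nondominant")


class TraceFormatError(ValueError):
    """Malformed trace file (bad header, columns, or cell)."""


class TraceValidationError(ValueError):
    """Structurally well-formed trace violating an invariant."""


class PenSample(NamedTuple):
    t: float  # ms since trace start
    x: float  # mm
    y: float  # mm
    pressure: float  # device units, >= 0


@dataclass(eq=False)
class Trace:
    """An ordered, validated pen trace with subject metadata.

    Channels are stored as parallel float arrays; ``samples`` exposes them
    as a list of :class:`PenSample` for row-wise access.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    subject_id: str = ""
    group: str = "unknown"
    hand: str = "dominant"
    device_pressure_max: float = 1023.0

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "pressure"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        issues = validate_trace(self)
        if issues:
            raise TraceValidationError("; ".join(issues))

    @classmethod
    def from_samples(cls, samples: Iterable[PenSample], **metadata) -> "Trace":
        rows = list(samples)
        arr = np.asarray(rows, dtype=float).reshape(-1, 4)
        return cls(t=arr[:, 0], x=arr[:, 1], y=arr[:, 2], pressure=arr[:, 3], **metadata)

    @property
    def samples(self) -> list[PenSample]:
        return [PenSample(*row) for row in zip(self.t, self.x, self.y, self.pressure)]

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def metadata(self) -> dict[str, str]:
        return {
            "device_pressure_max": repr(float(self.device_pressure_max)),
            "group": self.group,
            "hand": self.hand,
            "subject_id": self.subject_id,
        }

    def replace_channels(self, **channels) -> "Trace":
        return replace(self, **channels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Trace):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.group == other.group
            and self.hand == other.hand
            and self.device_pressure_max == other.device_pressure_max
            and all(
                np.array_equal(getattr(self, k), getattr(other, k))
                for k in ("t", "x", "y", "pressure")
            )
        )


def validate_trace(trace) -> list[str]:
    """Check every trace invariant; return one message per violation.

    An empty list means the trace is valid.  Messages name the invariant and
    the first offending sample index.
    """
    issues: list[str] = []
    n = len(trace.t)
    if n < 2:
        issues.append(f"trace must have >= 2 samples, has {n}")
    for name in ("t", "x", "y", "pressure"):
        arr = np.asarray(getattr(trace, name), dtype=float)
        if len(arr) != n:
            issues.append(f"channel {name} has length {len(arr)} != {n}")
            continue
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            issues.append(f"non-finite {name} at index {bad[0]}")
    if n and np.isfinite(trace.t).all():
        if np.any(trace.t < 0):
            idx = int(np.flatnonzero(trace.t < 0)[0])
            issues.append(f"negative time at index {idx}")
        nonmono = np.flatnonzero(np.diff(trace.t) <= 0)
        if nonmono.size:
            issues.append(f"time not strictly increasing at index {int(nonmono[0]) + 1}")
    if n and np.isfinite(trace.pressure).all():
        neg = np.flatnonzero(trace.pressure < 0)
        if neg.size:
            issues.append(f"negative pressure at index {int(neg[0])}")
    if trace.group not in _GROUPS:
        issues.append(f"group must be one of {_GROUPS}, got {trace.group!r}")
    if trace.hand not in _HANDS:
        issues.append(f"hand must be one of {_HANDS}, got {trace.hand!r}")
    return issues


def _fmt(v: float) -> str:
    # repr of the float round-trips exactly; render integral values compactly
    fv = float(v)
    if fv.is_integer() and abs(fv) < 1e16:
        return str(int(fv))
    return repr(fv)


def write_trace_csv(trace: Trace, path) -> None:
    """Write a trace; byte-identical output for identical inputs."""
    buf = io.StringIO()
    for key, value in sorted(trace.metadata().items()):
        buf.write(f"# {key}={value}\n")
    buf.write(_HEADER + "\n")
    for row in zip(trace.t, trace.x, trace.y, trace.pressure):
        buf.write(",".join(_fmt(v) for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def read_trace_csv(path) -> Trace:
    """Read and validate a trace file written by :func:`write_trace_csv`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    meta: dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i][1:].strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
        i += 1
    if i >= len(lines) or lines[i].strip() != _HEADER:
        got = lines[i].strip() if i < len(lines) else "<end of file>"
        raise TraceFormatError(f"{path}: expected header {_HEADER!r}, got {got!r}")
    i += 1
    rows = []
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != 4:
            raise TraceFormatError(f"{path}:{lineno}: expected 4 columns, got {len(cells)}")
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise TraceFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if len(rows) < 2:
        raise TraceValidationError(f"{path}: data section has {len(rows)} rows; need >= 2")
    arr = np.asarray(rows, dtype=float)
    kwargs = {}
    if "subject_id" in meta:
        kwargs["subject_id"] = meta["subject_id"]
    if "group" in meta:
        kwargs["group"] = meta["group"]
    if "hand" in meta:
        kwargs["hand"] = meta["hand"]
    if "device_pressure_max" in meta:
        kwargs["device_pressure_max"] = float(meta["device_pressure_max"])
    return Trace(t=arr[:, 0], x=arr[:, 1], y=arr[:, 2], pressure=arr[:, 3], **kwargs)
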