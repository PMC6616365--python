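"""The four dexterity variables extracted from a pen trace.

Over the analysis window (the central cycles of the task figure) each trace
is summarized by:

* **tracing accuracy** — the summed distance (mm) between every recorded
  sample and the task curve.  Larger values mean the trace deviated more.
* **pressure change sum** — the summed absolute change in pen pressure
  between consecutive samples (device units).  Rough, hesitant tracing
  raises it.  Note this is a sum of *changes*; the raw sum of pressures is
  available separately as :func:`pressure_total` for sensitivity analyses.
* **pressure change max** — the largest single-step pressure change; a pen
  lift (pressure dropping to 0) dominates this variable.
* **duration** — elapsed time (s) between the first and last sample of the
  clipped trace.

Sums run over recorded samples with no resampling, so the effective
sampling rate is part of the measurement and travels with the trace
metadata.  Clipping keeps the contiguous run of samples between the first
x-threshold crossings; boundary positions are not interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_geometry import (
    TaskFigure,
    XWindow,
    analysis_window,
    cycle_windows,
    nearest_distances,
    task_curve_y,
)
from .trace_io import Trace

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "clip_to_window",
    "tracing_accuracy",
    "pressure_change_sum",
    "pressure_change_max",
    "pressure_total",
    "tracing_duration",
    "extract_features",
    "cycle_features",
    "feature_table",
    "read_feature_table",
    "write_feature_table",
]

#: fixed input order of the scoring network
FEATURE_NAMES = (
    "tracing_accuracy",
    "pressure_change_sum",
    "pressure_change_max",
    "duration",
)


@dataclass(frozen=True)
class FeatureVector:
    """The four dexterity variables for one trace segment."""

    tracing_accuracy: float  # mm, summed over samples
    pressure_change_sum: float  # device units
    pressure_change_max: float  # device units
    duration: float  # seconds
    n_samples: int
    window: XWindow

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < 0):
            raise ValueError(f"dexterity variables must be >= 0, got {vals}")
        if self.pressure_change_max > self.pressure_change_sum + 1e-9:
            raise ValueError("pressure_change_max cannot exceed pressure_change_sum")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    def as_array(self) -> np.ndarray:
        """Values in the fixed network-input order of :data:`FEATURE_NAMES`."""
        return np.array(
            [
                self.tracing_accuracy,
                self.pressure_change_sum,
                self.pressure_change_max,
                self.duration,
            ]
        )


def clip_to_window(trace: Trace, window: XWindow) -> Trace:
    """Contiguous run from the first sample with x >= x_start to the last with x <= x_end."""
    inside = np.flatnonzero((trace.x >= window.x_start) & (trace.x <= window.x_end))
    if inside.size < 2:
        raise ValueError(
            f"window [{window.x_start:g}, {window.x_end:g}] contains "
            f"{inside.size} samples; need >= 2"
        )
    lo, hi = int(inside[0]), int(inside[-1]) + 1
    return trace.replace_channels(
        t=trace.t[lo:hi], x=trace.x[lo:hi], y=trace.y[lo:hi], pressure=trace.pressure[lo:hi]
    )


def tracing_accuracy(trace: Trace, figure: TaskFigure, mode: str = "nearest") -> float:
    """Summed sample-to-curve distance in mm (larger = worse tracing)."""
    if mode == "vertical":
        d = np.abs(trace.y - task_curve_y(figure, trace.x))
    elif mode == "nearest":
        d = nearest_distances(figure, trace.x, trace.y)
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return float(np.sum(d))


def _require_two(trace: Trace) -> None:
    if trace.n_samples < 2:
        raise ValueError(f"need >= 2 samples, got {trace.n_samples}")


def pressure_change_sum(trace: Trace) -> float:
    """Sum of |delta pressure| over consecutive samples (device units)."""
    _require_two(trace)
    return float(np.sum(np.abs(np.diff(trace.pressure))))


def pressure_change_max(trace: Trace) -> float:
    """Largest single-step |delta pressure|; pen lifts spike this."""
    _require_two(trace)
    return float(np.max(np.abs(np.diff(trace.pressure))))


def pressure_total(trace: Trace) -> float:
    """Raw sum of pressures (device units); not a network input."""
    return float(np.sum(trace.pressure))


def tracing_duration(trace: Trace) -> float:
    """Elapsed time in seconds between first and last sample."""
    _require_two(trace)
    return float((trace.t[-1] - trace.t[0]) / 1000.0)


def extract_features(
    trace: Trace, figure: TaskFigure | None = None, mode: str = "nearest"
) -> FeatureVector:
    """Clip the trace to the analysis window and compute all four variables."""
    figure = figure or TaskFigure()
    window = analysis_window(figure)
    clipped = clip_to_window(trace, window)
    return FeatureVector(
        tracing_accuracy=tracing_accuracy(clipped, figure, mode),
        pressure_change_sum=pressure_change_sum(clipped),
        pressure_change_max=pressure_change_max(clipped),
        duration=tracing_duration(clipped),
        n_samples=clipped.n_samples,
        window=window,
    )


def cycle_features(
    trace: Trace, figure: TaskFigure | None = None, mode: str = "nearest"
) -> list[FeatureVector]:
    """One FeatureVector per one-wavelength cycle window, in tracing order."""
    figure = figure or TaskFigure()
    out = []
    for i, window in enumerate(cycle_windows(figure)):
        try:
            clipped = clip_to_window(trace, window)
        except ValueError as exc:
            raise ValueError(f"cycle {i}: {exc}") from None
        out.append(
            FeatureVector(
                tracing_accuracy=tracing_accuracy(clipped, figure, mode),
                pressure_change_sum=pressure_change_sum(clipped),
                pressure_change_max=pressure_change_max(clipped),
                duration=tracing_duration(clipped),
                n_samples=clipped.n_samples,
                window=window,
            )
        )
    return out


# ---------------------------------------------------------------------------
# feature tables: subject_id, group, then the four variables


def feature_table(
    subject_ids, groups, vectors: list[FeatureVector]
) -> pd.DataFrame:
    """Assemble the standard feature-table DataFrame."""
    rows = []
    for sid, grp, fv in zip(subject_ids, groups, vectors, strict=True):
        row = {"subject_id": sid, "group": grp}
        row.update({k: getattr(fv, k) for k in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "group", *FEATURE_NAMES])


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table CSV; external tables must be coerced to this schema."""
    df = pd.read_csv(path)
    missing = {"subject_id", "group", *FEATURE_NAMES} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: feature table missing columns {sorted(missing)}")
    bad = set(df["group"]) - {"patient", "control"}
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    return df[["subject_id", "group", *FEATURE_NAMES]]
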