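"""Seeded synthetic pen traces for healthy and motor-impaired tracers.

Real traces of the sine-wave task are not publicly available, so every
pipeline stage is exercised on simulated ones.  A trace is generated by
moving the pen tip along x at a per-trace speed, sampling at a fixed rate,
and writing y as the task curve plus white tracking noise plus a sinusoidal
tremor with seeded phase.  Pressure is white around a mean; pen lifts are
Poisson-distributed events that clamp pressure to zero for a fixed
duration, producing the sudden pressure changes that the max-change
variable keys on.

The default profiles encode the qualitative patient/control contrast seen
clinically: the impaired tracer deviates more, trembles, occasionally
lifts the pen, presses more erratically and moves at half the speed.  A
lognormal per-trace multiplier (``subject_variability``) spreads
deviation, tremor, lift rate and speed across subjects so that group
distributions overlap realistically instead of collapsing to points.
Defaults are calibrated only to reproduce orderings and separability of
the dexterity variables, not any particular cohort's means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .task_geometry import TaskFigure, task_curve_y
from .trace_io import Trace

__all__ = [
    "MotorProfile",
    "CohortSpec",
    "simulate_trace",
    "default_profiles",
    "simulate_cohort",
    "child_seed",
]


@dataclass(frozen=True)
class MotorProfile:
    """Population-level motor characteristics of one group of tracers."""

    deviation_sd: float  # mm, white tracking noise
    tremor_amplitude: float  # mm
    tremor_freq: float  # Hz
    lift_rate: float  # expected pen lifts per trace
    lift_duration: float  # ms
    speed: float  # mm/s along x
    pressure_mean: float  # device units
    pressure_sd: float  # device units
    sample_rate: float = 100.0  # Hz
    subject_variability: float = 0.35  # lognormal CV across traces

    def __post_init__(self) -> None:
        for name in (
            "deviation_sd",
            "tremor_amplitude",
            "tremor_freq",
            "lift_rate",
            "lift_duration",
            "pressure_mean",
            "pressure_sd",
            "subject_variability",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.speed > 0:
            raise ValueError("speed must be > 0")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MotorProfile":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class CohortSpec:
    """A two-group cohort: sizes, group profiles, and the root seed."""

    n_patients: int
    n_controls: int
    patient_profile: MotorProfile
    control_profile: MotorProfile
    seed: int

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_patients + self.n_controls == 0:
            raise ValueError("cohort must contain at least one subject")


def default_profiles() -> tuple[MotorProfile, MotorProfile]:
    """(control, patient) default profiles.

    The patient profile has deviation, tremor amplitude, lift rate and
    inverse speed all at least twice the control values.
    """
    control = MotorProfile(
        deviation_sd=0.8,
        tremor_amplitude=0.0,
        tremor_freq=0.0,
        lift_rate=0.0,
        lift_duration=120.0,
        speed=40.0,
        pressure_mean=500.0,
        pressure_sd=8.0,
    )
    patient = MotorProfile(
        deviation_sd=2.5,
        tremor_amplitude=1.5,
        tremor_freq=4.0,
        lift_rate=2.0,
        lift_duration=120.0,
        speed=20.0,
        pressure_mean=500.0,
        pressure_sd=25.0,
    )
    return control, patient


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def simulate_trace(
    figure: TaskFigure,
    profile: MotorProfile,
    seed: int,
    subject_id: str = "",
    group: str = "unknown",
) -> Trace:
    """One deterministic trace of the full figure under a motor profile."""
    rng = np.random.default_rng(seed)
    # per-trace draws of the heterogeneous parameters
    dev_sd = profile.deviation_sd * _lognormal_factor(rng, profile.subject_variability)
    tremor_amp = profile.tremor_amplitude * _lognormal_factor(rng, profile.subject_variability)
    lift_rate = profile.lift_rate * _lognormal_factor(rng, profile.subject_variability)
    speed = profile.speed * _lognormal_factor(rng, profile.subject_variability)

    lo, hi = figure.span
    total_time_s = (hi - lo) / speed
    n = int(np.floor(total_time_s * profile.sample_rate)) + 1
    if n < 2:
        raise ValueError("profile produces fewer than 2 samples over the figure")
    t_s = np.arange(n) / profile.sample_rate
    x = lo + speed * t_s
    x = np.minimum(x, hi)  # guard float overshoot at the last sample
    phase = rng.uniform(0.0, 2.0 * np.pi)
    y = (
        task_curve_y(figure, x)
        + rng.normal(0.0, dev_sd, size=n)
        + tremor_amp * np.sin(2.0 * np.pi * profile.tremor_freq * t_s + phase)
    )
    pressure = np.clip(rng.normal(profile.pressure_mean, profile.pressure_sd, size=n), 0.0, None)

    n_lifts = rng.poisson(lift_rate)
    t_ms = t_s * 1000.0
    for start in rng.uniform(0.0, t_ms[-1], size=n_lifts):
        mask = (t_ms >= start) & (t_ms < start + profile.lift_duration)
        pressure[mask] = 0.0

    return Trace(
        t=t_ms,
        x=x,
        y=y,
        pressure=pressure,
        subject_id=subject_id,
        group=group,
        hand="dominant",
    )


def child_seed(root_seed: int, index: int) -> int:
    """Deterministic, disjoint per-subject seed derived from the root seed."""
    return int(np.random.SeedSequence([root_seed, index]).generate_state(1)[0] % 2**31)


def simulate_cohort(
    figure: TaskFigure, spec: CohortSpec
) -> tuple[list[Trace], pd.DataFrame]:
    """All traces of a two-group cohort plus its manifest.

    Subjects are numbered patients first; each gets its own child seed so
    the cohort is reproducible regardless of generation order.
    """
    traces: list[Trace] = []
    rows = []
    for i in range(spec.n_patients + spec.n_controls):
        is_patient = i < spec.n_patients
        group = "patient" if is_patient else "control"
        sid = f"{'P' if is_patient else 'C'}{i if is_patient else i - spec.n_patients:03d}"
        seed_i = child_seed(spec.seed, i)
        traces.append(
            simulate_trace(
                figure,
                spec.patient_profile if is_patient else spec.control_profile,
                seed=seed_i,
                subject_id=sid,
                group=group,
            )
        )
        rows.append({"subject_id": sid, "group": group, "seed": seed_i})
    return traces, pd.DataFrame(rows, columns=["subject_id", "group", "seed"])
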