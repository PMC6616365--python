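import numpy as np
import pytest

from sttkit import TaskFigure, Trace, task_curve_y


@pytest.fixture
def figure() -> TaskFigure:
    """The default printed task: 4 cycles, 35 mm amplitude, 62 mm wavelength."""
    return TaskFigure()


def make_on_curve_trace(
    figure: TaskFigure,
    n: int = 200,
    pressure: float = 500.0,
    dt_ms: float = 10.0,
    y_offset: float = 0.0,
    group: str = "unknown",
) -> Trace:
    """A trace sampled exactly on the task curve (plus optional y offset)."""
    lo, hi = figure.span
    x = np.linspace(lo, hi, n)
    return Trace(
        t=np.arange(n) * dt_ms,
        x=x,
        y=task_curve_y(figure, x) + y_offset,
        pressure=np.full(n, float(pressure)),
        subject_id="fixture",
        group=group,
    )


@pytest.fixture
def on_curve_trace(figure) -> Trace:
    return make_on_curve_trace(figure)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
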