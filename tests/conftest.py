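import numpy as np
import pytest

from stepcal.trajectory import Trajectory


@pytest.fixture
def line_trajectory():
    """Trajectory factory: y(t) = intercept + slope * t on days 0..30."""

    def make(intercept=0.0, slope=1.0, name="y", step=1.0):
        t = np.arange(0.0, 30.0 + 1e-9, step)
        return Trajectory(times=t, variables={name: intercept + slope * t})

    return make


@pytest.fixture
def constant_trajectory():
    def make(value, name="y", t_end=10.0):
        t = np.linspace(0.0, t_end, 21)
        return Trajectory(times=t, variables={name: np.full_like(t, float(value))})

    return make
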