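import numpy as np
import pytest

from archflow.cohort import cohort_fixture
from archflow.waveform import FlowWaveform, gen_inflow_waveform


@pytest.fixture(scope="session")
def inflow():
    """Reference pulsatile inflow: 5 L/min mean, 20 L/min peak, 1 s cycle."""
    return gen_inflow_waveform(5.0, 20.0, period=1.0, n_samples=256, seed=1)


@pytest.fixture(scope="session")
def cohort():
    return cohort_fixture()


def constant_waveform(flow_l_min: float, period: float = 1.0, n: int = 101) -> FlowWaveform:
    t = np.linspace(0.0, period, n)
    return FlowWaveform(t, np.full(n, flow_l_min / 60000.0), period)


@pytest.fixture(scope="session")
def const_inflow():
    """Constant 5 L/min inflow (83.33 mL/s)."""
    return constant_waveform(5.0)
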