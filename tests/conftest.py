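import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import socekit as sk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def protocol():
    """Standard four-phase SOCE protocol (60/240/300/120 s, 1 mM re-addition)."""
    return sk.build_standard_protocol()


@pytest.fixture(scope="session")
def noiseless_params():
    return sk.CellParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_trace(protocol, noiseless_params):
    return sk.simulate_cell(noiseless_params, protocol)


def make_trace(protocol, ca_fn, dt=2.0, cell_id="c0", population="pop"):
    """Construct a trace from a vectorised function of time."""
    t = protocol.start_s + np.arange(int(round(protocol.duration_s / dt)) + 1) * dt
    return sk.CalciumTrace(cell_id, population, t, np.asarray(ca_fn(t), dtype=float), protocol)


@pytest.fixture(scope="session")
def trace_factory():
    return make_trace
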