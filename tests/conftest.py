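import numpy as np
import pytest

from nmjhomeo.plasticity import (
    BurstSchedule,
    calibrate_rule,
    default_cell,
    default_synapse,
)


@pytest.fixture(scope="session")
def cell():
    return default_cell()


@pytest.fixture(scope="session")
def rule(cell):
    # deterministic package calibration; cached across the session
    return calibrate_rule(cell=cell)


@pytest.fixture(scope="session")
def synapse(cell):
    return default_synapse(cell)


@pytest.fixture
def short_burst():
    return BurstSchedule(n_bursts=3, pulses_per_burst=5, hz=30.0, interval_s=30.0)
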