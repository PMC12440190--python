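import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("spikesde", deadline=None, derandomize=True)
settings.load_profile("spikesde")

from spikesde import (
    ControlSignal,
    SimulationGrid,
    SpikeTarget,
    preset_params,
    sample_noise,
)


@pytest.fixture
def rs():
    return preset_params("RS")


@pytest.fixture
def grid_5ms():
    return SimulationGrid(h=0.1, t_size=50)


@pytest.fixture
def grid_10ms():
    return SimulationGrid(h=0.1, t_size=100)


@pytest.fixture
def toy_target():
    return SpikeTarget(times=np.array([1.5, 3.0]), horizon=5.0)


@pytest.fixture
def toy_control(grid_5ms):
    # constant drive strong enough that the rectified drift stays active
    return ControlSignal.constant(grid_5ms, 15.0)


@pytest.fixture
def frozen_noise(grid_5ms):
    return sample_noise(grid_5ms, 1.0, 42)
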