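import dataclasses

import numpy as np
import pytest

from cidot.config import PipelineConfig, tiny_config
from cidot.pipeline import World
from cidot.synthetic_data import RawRun, StimulusSchedule


@pytest.fixture(scope="session")
def default_world() -> World:
    """Study-scale probe (24 sources / 38 detectors, 3 mm grid)."""
    return World.from_config(PipelineConfig())


@pytest.fixture(scope="session")
def tiny_world() -> World:
    """Reduced probe for loops that rebuild operators repeatedly."""
    return World.from_config(tiny_config())


@pytest.fixture
def quiet_noise(default_world):
    """Noise config with white noise and drift off (physiology retained)."""
    return dataclasses.replace(default_world.config.noise,
                               white_od_sd=0.0, drift_od_sd=0.0)


def make_raw(levels: np.ndarray, rate_hz: float = 10.0,
             task: str = "rest", subject_id: str = "s0") -> RawRun:
    """Wrap a bare level matrix in a RawRun with a matching rest schedule."""
    levels = np.asarray(levels, float)
    sch = StimulusSchedule([], 0, levels.shape[1] / rate_hz, task)
    return RawRun(levels, rate_hz, sch, subject_id)
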