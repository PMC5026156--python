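import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "nirsrel",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("nirsrel")

from nirsrel.config import (AmplitudeModel, MotionModel, PipelineConfig,
                            SimulationConfig, SystemicModel)


@pytest.fixture
def rng():
    return np.random.default_rng(20161001)


@pytest.fixture
def small_config():
    """Compact cohort: 3 subjects x 2 sessions, 8 channels, short blocks."""
    return SimulationConfig(
        n_subjects=3,
        n_sessions=2,
        n_channels=8,
        conditions=("A-ONLY", "V-ONLY", "AV"),
        blocks_per_condition=2,
        block_duration_s=12.0,
        rest_range_s=(8.0, 12.0),
        control_trial_count=1,
        roi_channels={"left": (1, 2, 3), "right": (4, 5, 6)},
        responsive_channels=(1, 2, 3, 4, 5, 6),
        seed=11,
    )


@pytest.fixture
def single_channel_config():
    """One responsive channel; convenient for component-level tests."""
    return SimulationConfig(
        n_subjects=1,
        n_channels=1,
        responsive_channels=(1,),
        roi_channels={"left": (1,), "right": (1,)},
        seed=3,
    )


@pytest.fixture
def quiet():
    """Suppress the degenerate-regressor warnings emitted on purpose."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def small_pipeline_config(small_config):
    return PipelineConfig(simulation=small_config, seed=11)
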