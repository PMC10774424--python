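import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from omrkit.synthetic_behavior import BehaviorProtocol, FishParams, simulate_session
from omrkit.synthetic_imaging import (
    BlockSchedule,
    ImagingProtocol,
    ImagingTrial,
    build_block_schedule,
)


@pytest.fixture(scope="session")
def control_session():
    """One full control session (5 conditions x 30 sets) with ground truth."""
    return simulate_session(BehaviorProtocol(), FishParams(), "control", seed=11)


@pytest.fixture(scope="session")
def small_lr_protocol():
    """Left/right-only protocol for quick directional statistics."""
    return BehaviorProtocol(conditions=("left", "right"), n_sets=15)


def make_schedule(stimuli, block="baseline"):
    """Hand-built imaging block schedule from an explicit stimulus list."""
    proto = ImagingProtocol()
    trials = [
        ImagingTrial(i, block, s, i * proto.trial_duration_s)
        for i, s in enumerate(stimuli)
    ]
    return BlockSchedule(
        experiment="acute",
        block_labels=[block],
        trials=trials,
        protocol=proto,
        washout_start_s=0.0,
    )


@pytest.fixture(scope="session")
def acute_schedule():
    return build_block_schedule("acute", n_washout_blocks=1, seed=3)
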