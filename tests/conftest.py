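import numpy as np
import pytest

from gaitfm import (
    ActivitySchedule,
    ActivitySegment,
    GaitProfile,
    preprocess,
    simulate_gait_recording,
)

SAMPLE_RATE = 100.0


@pytest.fixture(scope="session")
def default_profile():
    return GaitProfile()


@pytest.fixture(scope="session")
def walk_recording():
    """30 s steady walk padded with 5 s rest, plus its ground truth."""
    profile = GaitProfile(step_time_mean=0.6, step_time_sd=0.01, noise_sd=0.02)
    schedule = ActivitySchedule.single_walk(30.0, pad=5.0)
    return simulate_gait_recording(profile, schedule, SAMPLE_RATE, seed=11)


@pytest.fixture(scope="session")
def walk_uniform(walk_recording):
    rec, truth = walk_recording
    return preprocess(rec), truth


@pytest.fixture(scope="session")
def mixed_schedule_recording():
    """Free-living-style day: walks, rests and a non-periodic burst."""
    profile = GaitProfile(step_time_mean=0.55, step_time_sd=0.02, noise_sd=0.02)
    schedule = ActivitySchedule(
        [
            ActivitySegment("rest", 12.0),
            ActivitySegment("walk", 20.0),
            ActivitySegment("rest", 10.0),
            ActivitySegment("random_movement", 12.0),
            ActivitySegment("rest", 10.0),
            ActivitySegment("walk", 65.0),
            ActivitySegment("rest", 10.0),
        ]
    )
    return simulate_gait_recording(profile, schedule, SAMPLE_RATE, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
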