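import numpy as np
import pytest

from skelkit import BodyDimensions, JointAngleSet, MotionConfig, forward_kinematics


@pytest.fixture(scope="session")
def dims() -> BodyDimensions:
    return BodyDimensions()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def rest_frame(dims):
    """Default standing pose facing the sensor."""
    return forward_kinematics(JointAngleSet(), dims)


def make_pose(dims=BodyDimensions(), **angles):
    """FK frame with the given angle overrides on the rest pose."""
    return forward_kinematics(JointAngleSet(dict(angles)), dims)


@pytest.fixture(scope="session")
def small_motion(dims):
    """A short, fully-deterministic synthetic capture (clean + truth)."""
    from skelkit import generate_motion

    cfg = MotionConfig(n_frames=60, seed=11, calibration_frames=10)
    return cfg, generate_motion(cfg, dims)
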