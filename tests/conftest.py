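import numpy as np
import pytest

from kinemimic import quat
from kinemimic.bodies import Pose, make_quadruped_fixture, make_worm_fixture


@pytest.fixture(scope="session")
def worm():
    return make_worm_fixture()


@pytest.fixture(scope="session")
def quad():
    return make_quadruped_fixture()


def sinusoid_trajectory(tree, n_frames, amplitude=0.5, root_height=0.25, phase_step=0.3):
    """Smooth, diverse whole-body trajectory within joint ranges."""
    lo, hi = tree.joint_ranges
    poses = []
    for k in range(n_frames):
        t = k / n_frames
        q = np.clip(amplitude * np.sin(2 * np.pi * t + phase_step * np.arange(tree.n_dof)), lo, hi)
        poses.append(
            Pose(
                np.array([0.2 * t, 0.05 * np.sin(5 * t), root_height + 0.02 * np.sin(3 * t)]),
                quat.from_axis_angle([0, 0, 1], 0.4 * t),
                q,
            )
        )
    return poses


@pytest.fixture
def rng():
    return np.random.default_rng(0)
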