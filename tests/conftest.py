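import numpy as np
import pytest

from roamdwell import AnalysisConfig, Trajectory


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_trajectory(
    x,
    y,
    animal_id="a1",
    frame_rate_hz=3.75,
    skeleton=None,
    bend_deg=None,
    time_s=None,
):
    """Build a Trajectory from coordinate lists with evenly spaced frames."""
    x = np.asarray(x, float)
    n = len(x)
    if time_s is None:
        time_s = np.arange(n) / frame_rate_hz
    return Trajectory(
        animal_id=animal_id,
        frame_index=np.arange(n),
        time_s=np.asarray(time_s, float),
        x_um=x,
        y_um=np.asarray(y, float),
        frame_rate_hz=frame_rate_hz,
        skeleton_um=skeleton,
        bend_deg=bend_deg,
    )


@pytest.fixture
def random_walk_trajectory(rng):
    n = 200
    steps = rng.normal(0, 40, size=(n, 2))
    pos = np.cumsum(steps, axis=0)
    return make_trajectory(pos[:, 0], pos[:, 1])
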