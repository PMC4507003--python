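import numpy as np
import pytest

from searchkin.protocols import continuous
from searchkin.simulate import Trajectory


@pytest.fixture
def no_bleach_continuous():
    return continuous(bleach_rate_continuous=0.0)


def make_track(x, y, dt=1.0 / 197.0, protocol=None, track_id=0):
    """Trajectory from coordinate arrays with a uniform frame interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    return Trajectory(
        track_id=track_id,
        frame_index=np.arange(n),
        t_s=np.arange(n) * dt,
        x_um=x,
        y_um=y,
        protocol=protocol,
    )


def brownian_track(n, D, dt=1.0 / 197.0, seed=0, sigma=0.0, protocol=None):
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((2, n - 1)) * np.sqrt(2.0 * D * dt)
    xy = np.concatenate([np.zeros((2, 1)), np.cumsum(steps, axis=1)], axis=1)
    if sigma > 0:
        xy = xy + rng.standard_normal(xy.shape) * sigma
    return make_track(xy[0], xy[1], dt=dt, protocol=protocol)
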