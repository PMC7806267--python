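import numpy as np
import pytest

from neuromast.track_geometry import AngleSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_angle_series(rng, n_frames=None, dt=3.0):
    """Random unwrapped-angle walks with per-frame steps well below 90 deg."""
    n = n_frames or int(rng.integers(10, 80))
    steps = rng.uniform(-30.0, 45.0, size=n - 1)
    unwrapped = np.concatenate([[0.0], np.cumsum(steps)])
    wrapped = (unwrapped + 180.0) % 360.0 - 180.0
    wrapped[np.isclose(wrapped, -180.0)] = 180.0
    times = np.arange(n) * dt
    return AngleSeries(times=times, theta_deg=wrapped, theta_unwrapped_deg=unwrapped)
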