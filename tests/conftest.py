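import numpy as np
import pandas as pd
import pytest

from tadtraj.core import Trajectory


def make_trajectory(
    xy,
    start="2015-02-01 09:00",
    step_minutes=40,
    waypoints=None,
    phase="TT",
    frog_id="F00",
    times=None,
):
    """Build a Trajectory from bare coordinates for unit tests."""
    xy = np.asarray(xy, dtype=float)
    if times is None:
        t0 = pd.Timestamp(start)
        times = [t0 + pd.Timedelta(minutes=step_minutes * i) for i in range(len(xy))]
    fixes = pd.DataFrame(
        {
            "frog_id": frog_id,
            "timestamp": pd.to_datetime(times),
            "x_m": xy[:, 0],
            "y_m": xy[:, 1],
            "tadpoles": np.nan,
            "behavior": "unknown",
        }
    )
    if waypoints is None:
        waypoints = np.array([xy[0], xy[-1]])
    return Trajectory(frog_id=frog_id, phase=phase, fixes=fixes, waypoints=waypoints)


@pytest.fixture
def trajectory_factory():
    return make_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20150212)
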