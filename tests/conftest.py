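import numpy as np
import pandas as pd
import pytest

from piipath import SimConfig, Trajectory, simulate


def make_trajectory(
    coords,
    animal_id="A1",
    interval=240.0,
    start="2020-01-01 01:00:00",
    valid=None,
):
    """Trajectory from a coordinate list; None entries are invalid fixes."""
    n = len(coords)
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * interval, unit="m")
    xs, ys, ok = [], [], []
    for i, c in enumerate(coords):
        if c is None:
            xs.append(np.nan), ys.append(np.nan), ok.append(False)
        else:
            xs.append(float(c[0])), ys.append(float(c[1])), ok.append(True)
    if valid is not None:
        ok = list(valid)
    fixes = pd.DataFrame(
        {"seq": np.arange(n), "timestamp": ts, "x": xs, "y": ys, "valid": ok}
    )
    return Trajectory(animal_id, fixes, interval)


@pytest.fixture
def traj_factory():
    return make_trajectory


@pytest.fixture(scope="session")
def sim180():
    """One 180-day default simulation shared across tests."""
    return simulate(SimConfig(seed=11, duration_days=180.0))


@pytest.fixture(scope="session")
def sim60():
    return simulate(SimConfig(seed=7, duration_days=60.0))
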