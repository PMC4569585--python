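import numpy as np
import pandas as pd
import pytest

from zosrec import synth
from zosrec.waves import BathymetryGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return synth.SynthConfig()


@pytest.fixture
def island_bathy():
    """A 21x21 water basin (2 m deep) ringed by land; cell 100 m.

    The center cell sits 1 km (10 cells) from land in the cardinal
    directions.
    """
    depth = np.full((21, 21), 2.0)
    depth[0, :] = depth[-1, :] = np.nan
    depth[:, 0] = depth[:, -1] = np.nan
    return BathymetryGrid(depth, cell=100.0)


@pytest.fixture
def open_east_bathy():
    """Water basin with land on north/south/west but an open eastern edge."""
    depth = np.full((21, 21), 2.0)
    depth[0, :] = depth[-1, :] = np.nan
    depth[:, 0] = np.nan
    return BathymetryGrid(depth, cell=100.0)


def make_wind_frame(times, speeds, directions, calm=None):
    calm = np.zeros(len(times), dtype=bool) if calm is None else np.asarray(calm)
    return pd.DataFrame({
        "time": times,
        "speed": np.asarray(speeds, dtype=float),
        "direction": np.asarray(directions, dtype=float),
        "calm": calm,
    })


@pytest.fixture
def hourly_january_winds():
    t = pd.date_range("2005-01-01", "2005-01-31 23:00", freq="h")
    speeds = 1.0 + np.arange(len(t)) % 100
    return make_wind_frame(t, speeds, np.full(len(t), 270.0))
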