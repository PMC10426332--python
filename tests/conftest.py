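import numpy as np
import pandas as pd
import pytest

from tempmort import synthetic as syn
from tempmort.model import RRCurve, make_temp_grid


@pytest.fixture(scope="session")
def city_spec():
    return syn.CityClimateSpec("testcity", latitude=40.0, mean_temp=12.0,
                               seasonal_amplitude=12.0)


@pytest.fixture(scope="session")
def surface():
    return syn.TrueRRSurface(mmt=18.0, hot_slope=0.03, cold_slope=0.008)


@pytest.fixture(scope="session")
def temps_14y(city_spec):
    return syn.gen_temperature(city_spec, 1987, 2000, seed=0)


def make_v_curve(mmt=18.0, hot=0.03, cold=0.008, tmin=-10.0, tmax=38.0,
                 city="toy", age="under75"):
    """Exact piecewise-linear V curve on a 0.1 degC grid through the MMT."""
    grid = make_temp_grid(tmin, tmax)
    # snap mmt onto the grid
    mmt = float(grid[np.argmin(np.abs(grid - mmt))])
    rr = np.where(grid >= mmt, 1 + hot * (grid - mmt), 1 + cold * (mmt - grid))
    return RRCurve(temp_grid=grid, rr=rr, mmt=mmt, city_id=city, age_group=age)


@pytest.fixture
def v_curve():
    return make_v_curve()


def daily_series(values, start="2000-01-01", name="x"):
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(values, index=idx, name=name)
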