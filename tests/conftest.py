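import datetime as dt

import pytest

from vitidss.disease import IncrementTable
from vitidss.synthetic_weather import WeatherGenParams
from vitidss.types import DailyWeather


def make_year(
    year=2021,
    tmean=20.0,
    tmin=15.0,
    tmax=25.0,
    precip=2.0,
    rh=80.0,
    site_id="site",
):
    """One full civil year of constant daily weather."""
    start = dt.date(year, 1, 1)
    n = (dt.date(year, 12, 31) - start).days + 1
    return [
        DailyWeather(
            site_id=site_id,
            date=start + dt.timedelta(days=i),
            tmin=tmin,
            tmax=tmax,
            tmean=tmean,
            precip=precip,
            rh_mean=rh,
        )
        for i in range(n)
    ]


def make_span(start, n, tmean=20.0, precip=0.0, rh=80.0, site_id="site"):
    """n contiguous constant days from an arbitrary start date."""
    return [
        DailyWeather(
            site_id=site_id,
            date=start + dt.timedelta(days=i),
            tmin=tmean - 5.0,
            tmax=tmean + 5.0,
            tmean=tmean,
            precip=precip,
            rh_mean=rh,
        )
        for i in range(n)
    ]


@pytest.fixture
def constant_year():
    return make_year()


@pytest.fixture
def gen_params():
    return WeatherGenParams(seed=7)


@pytest.fixture
def toy_table():
    """Single-cell increment table: 5 %/day everywhere in range."""
    return IncrementTable(temp_edges=(0.0, 40.0), rh_edges=(0.0, 101.0), increments=((5.0,),))
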