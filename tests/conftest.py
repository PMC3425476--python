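import datetime

import pytest

from pinewater.architecture import BranchingRules
from pinewater.growth import PlantParams
from pinewater.soil import SoilParams
from pinewater.synthetic import WeatherSpec, synth_weather, synth_weather_years
from pinewater.weather import SiteInfo, WeatherDay


@pytest.fixture(scope="session")
def site():
    return SiteInfo()


@pytest.fixture(scope="session")
def soil():
    return SoilParams()


@pytest.fixture(scope="session")
def rules():
    return BranchingRules()


@pytest.fixture(scope="session")
def params():
    return PlantParams()


@pytest.fixture(scope="session")
def weather_year():
    """One synthetic weather year in the semi-arid reference regime."""
    return synth_weather(WeatherSpec(seed=7))


@pytest.fixture(scope="session")
def weather_years():
    """Six synthetic years mirroring the 2001-2006 annual statistics."""
    return synth_weather_years(seed=1)


def constant_day(
    date=datetime.date(2005, 6, 1),
    t_mean=15.0,
    t_max=20.0,
    t_min=10.0,
    rh_mean=0.6,
    sunshine=8.0,
    wind=2.0,
    pressure=100.0,
    precip=0.0,
):
    return WeatherDay(
        date=date, t_mean=t_mean, t_max=t_max, t_min=t_min, rh_mean=rh_mean,
        sunshine=sunshine, wind=wind, pressure=pressure, precip=precip,
    )


@pytest.fixture(scope="session")
def constant_weather_year():
    """A full constant-weather year: mild, 2 mm rain every day."""
    start = datetime.date(2005, 1, 1)
    return [
        constant_day(date=start + datetime.timedelta(days=i), precip=2.0)
        for i in range(365)
    ]
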