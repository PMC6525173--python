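import datetime as dt

import pytest

from phenoflow.soil import SoilLayer, SoilProfile
from phenoflow.weather import DailyWeather, WeatherSeries


def make_constant_weather(
    tmax=15.0,
    tmin=5.0,
    rain=0.0,
    n_days=400,
    latitude=-26.5,
    start=dt.date(2015, 5, 1),
    irrigation=0.0,
):
    records = tuple(
        DailyWeather(
            date=start + dt.timedelta(days=i),
            tmax=tmax,
            tmin=tmin,
            rain=rain,
            irrigation=irrigation,
        )
        for i in range(n_days)
    )
    return WeatherSeries(latitude=latitude, records=records)


def make_two_layer_profile(
    thickness_cm=30.0, ll15=0.15, dul=0.30, sat=0.36, air_dry=0.10,
    swcon=0.3, kl=0.06,
):
    layers = (
        SoilLayer(0.0, thickness_cm, ll15, dul, sat, air_dry, swcon, kl),
        SoilLayer(thickness_cm, 2 * thickness_cm, ll15, dul, sat, air_dry, swcon, kl),
    )
    return SoilProfile(layers=layers)


@pytest.fixture
def constant_weather():
    return make_constant_weather()


@pytest.fixture
def two_layer_profile():
    return make_two_layer_profile()
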