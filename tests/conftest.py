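import datetime as dt

import pytest

from wheatwater import (
    ClimateParams,
    SiteMetadata,
    fill_solar_from_sunshine,
    generate_synthetic_weather,
)

# Experimental-station geography: Xinxiang, northern Henan (35.3 N, 73.2 m)
XINXIANG = SiteMetadata("XINX", latitude=35.3, longitude=113.9, elevation=73.2)

# Winter-wheat season window used throughout: sowing 10/18 to maturity 06/05
SEASON_START = dt.date(2015, 10, 18)
SEASON_DAYS = 232  # 10/18/2015 .. 06/05/2016 inclusive


@pytest.fixture(scope="session")
def site():
    return XINXIANG


@pytest.fixture(scope="session")
def season_weather(site):
    """One synthetic winter-wheat season of daily weather (seeded)."""
    return generate_synthetic_weather(
        site, SEASON_START, SEASON_DAYS, seed=42, climate=ClimateParams()
    )


@pytest.fixture(scope="session")
def season_weather_srad(season_weather, site):
    """Same season with solar radiation filled from sunshine hours."""
    return fill_solar_from_sunshine(season_weather, site)
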