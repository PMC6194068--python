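"""Compare the three daily reference-evapotranspiration models.

Runs Priestley-Taylor (DSSAT routine), FAO-56 Penman-Monteith and
Hargreaves (suggested global coefficients) over one synthetic season and
prints seasonal totals. Penman-Monteith is the standard; Hargreaves needs
only temperature and astronomical radiation, which is why it is the model
worth calibrating for data-sparse or future-scenario work.
"""

import datetime as dt

from wheatwater import (
    SiteMetadata,
    et0_hargreaves,
    et0_penman_monteith,
    et0_priestley_taylor,
    fill_solar_from_sunshine,
    generate_synthetic_weather,
)
from wheatwater.radiation import extraterrestrial_radiation
from wheatwater.weatherio import day_of_year, days_in_year

site = SiteMetadata("XINX", latitude=35.3, elevation=73.2)
weather = fill_solar_from_sunshine(
    generate_synthetic_weather(site, dt.date(2015, 10, 18), 232, seed=42), site
)

pt = sum(et0_priestley_taylor(r) for r in weather)
pm = sum(et0_penman_monteith(r, site) for r in weather)
hs = sum(
    et0_hargreaves(
        r.tmax, r.tmin,
        extraterrestrial_radiation(
            site.latitude_rad, day_of_year(r.date), days_in_year(r.date.year)
        ),
    )
    for r in weather
)

print(f"seasonal ET0, Penman-Monteith : {pm:7.1f} mm")
print(f"seasonal ET0, Hargreaves      : {hs:7.1f} mm")
print(f"seasonal ET0, Priestley-Taylor: {pt:7.1f} mm")
# Hargreaves lands near Penman-Monteith; the Priestley-Taylor total is far
# smaller because the published equilibrium-ET coefficient pairs with
# radiation in langleys, not MJ (see docs/methods.md) - plan comparisons
# therefore use ratios, never PT absolute magnitudes.
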