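"""Generate a seeded synthetic winter-wheat season of daily weather.

The generator emulates a temperate continental plain: sinusoidal annual
temperature with AR(1) anomalies, monsoon-concentrated intermittent rain,
and sunshine bounded by the astronomical daylength.
"""

import datetime as dt

from wheatwater import ClimateParams, SiteMetadata, generate_synthetic_weather

site = SiteMetadata("XINX", latitude=35.3, longitude=113.9, elevation=73.2)
records = generate_synthetic_weather(
    site,
    start_date=dt.date(2015, 10, 18),  # sowing
    n_days=232,                        # through maturity on 06/05
    seed=42,
    climate=ClimateParams(),           # 14.1 degC mean, ~580 mm/yr
)

total_rain = sum(r.precip for r in records)
wet_days = sum(r.precip > 0 for r in records)
print(f"{len(records)} days from {records[0].date} to {records[-1].date}")
print(f"seasonal precipitation: {total_rain:.1f} mm over {wet_days} wet days")
print(f"coldest tmin: {min(r.tmin for r in records):.1f} degC, "
      f"warmest tmax: {max(r.tmax for r in records):.1f} degC")
# Expect a winter-wheat season: ~150-250 mm of rain, winter minima well
# below zero, and a warm ripening period in late May.
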