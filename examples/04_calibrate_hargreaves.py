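"""Calibrate the Hargreaves model against Penman-Monteith for one station.

Fits (K, n, Toff) by bounded nonlinear least squares on daily residuals,
starting from the suggested global values (0.0023, 0.5, 17.8), and reports
fit statistics. With several seasons of weather this is exactly the
per-station regional-calibration workflow.
"""

import datetime as dt

from wheatwater import (
    SiteMetadata,
    calibrate_hargreaves,
    fill_solar_from_sunshine,
    generate_synthetic_weather,
)

site = SiteMetadata("XINX", latitude=35.3, elevation=73.2)
# three years of daily weather for a stable fit
weather = fill_solar_from_sunshine(
    generate_synthetic_weather(site, dt.date(2013, 1, 1), 3 * 365, seed=7), site
)

result = calibrate_hargreaves(weather, site)
p = result.params
print(f"fitted K    = {p.K:.5f}  (start 0.00230)")
print(f"fitted n    = {p.n_exp:.4f}   (start 0.5000)")
print(f"fitted Toff = {p.T_off:.2f}    (start 17.80)")
print(f"R^2 vs P-M  = {result.stats.r2:.3f}")
print(f"RMSE        = {result.stats.rmse:.3f} mm/d "
      f"(residual std error {result.residual_std_error:.3f})")
print(f"converged   = {result.converged} after {result.iterations} evaluations")
# The fitted triple replaces the global coefficients wherever only
# temperature records are trustworthy (e.g. downscaled future scenarios).
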