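# Methods

This note documents the models, the defaults and the numerical choices
behind `wheatwater`, and what the synthetic-data layer does and does not
establish about real data.

## Reference evapotranspiration

### Priestley–Taylor (DSSAT routine)

ET0 = α(T_max) · EEQ, with

EEQ = S_R · (2.04×10⁻⁴ − 1.83×10⁻⁴ · A_albedo) · (0.6 T_max + 0.4 T_min + 29)

and the advectivity coefficient

- α = 0.01 · e^{0.18 (T_max + 20)} for T_max < 5 °C,
- α = 1.1 for 5 ≤ T_max ≤ 35 °C,
- α = 1.1 + 0.05 (T_max − 35) for T_max > 35 °C.

The temperature threshold is interpreted as T_max, consistent with both
branch formulas being written in T_max. α is continuous at 35 °C but jumps
at 5 °C (0.01 e^{4.5} ≈ 0.900 → 1.1); the jump is a property of the
published piecewise definition and is asserted, not smoothed. Negative
intermediate ET0 is floored at zero.

**Known limitation — units of the EEQ coefficient.** In the DSSAT source
the 2.04×10⁻⁴ coefficient multiplies radiation in langleys (SLANG =
SRAD × 23.923); applied to S_R in MJ m⁻² d⁻¹, as implemented here to match
the published SI statement of the formula and its worked value
(20 × 2.04×10⁻⁴ × 50 = 0.204 mm), Priestley–Taylor ET0 is roughly 24×
smaller than Penman–Monteith in absolute terms. Every cross-plan result in
this package therefore uses ratios and factorization (Plan 2 / Plan 1 =
Kc), never PT absolute magnitudes; users needing physically scaled PT
values should multiply S_R by 23.923 beforehand.

The default albedo is 0.23, the reference-crop convention.

### FAO-56 Penman–Monteith

The daily form with standard auxiliary terms: e⁰(T) by Tetens; e_s the mean
of e⁰ at T_max and T_min; e_a = RH_mean/100 · e_s (clipped at e_s); Δ at
T_mean; γ = 0.000665 · P(z) with barometric pressure from elevation; net
radiation R_n = 0.77 R_s − R_nl with the longwave term using clear-sky
radiation R_so = (0.75 + 2×10⁻⁵ z) R_a and the ratio R_s/R_so capped at 1;
soil heat flux G = 0 at the daily step. Negative winter values are floored
at zero with a debug log. The implementation is cross-checked against an
independently written transliteration of the same published procedure to
0.01 mm d⁻¹ over 1000 random admissible days; that oracle lives in the test
suite and shares no code with the implementation.

### Hargreaves

ET0 = (K/λ) (T_max − T_min)ⁿ (T_mean + T_off) R_a, λ = 2.45 MJ kg⁻¹.
The diurnal-range base (T_max − T_min)ⁿ is the standard Hargreaves–Samani
form and the default; a `strict_printed_sum` switch evaluates
(T_max + T_min)ⁿ for auditing against sources that print the sum, which is
retained because the printed sum makes the exponent unidentifiable under
calibration (the sum and the mean-temperature factor are collinear) and
contradicts the formula's rationale of using the diurnal range as a
radiation proxy.

## Calibration

(K, n, T_off) are fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`) on daily residuals HS − PM, unweighted,
starting from (0.0023, 0.5, 17.8). Bounds: K ∈ (0, 0.05], n ∈ (0, 1.5],
T_off ∈ [0, 50]. Tolerances 10⁻¹⁰ on the objective, evaluation cap 500;
the solver path is deterministic. Days with zero diurnal range are excluded
(the n-gradient of (T_max−T_min)ⁿ is unbounded there). The residuals use
the unfloored Hargreaves expression so the objective stays smooth.
Calibration is per station; multi-station work is a loop over inputs.
Reported statistics: R² (squared Pearson correlation — affine-invariant,
undefined and erroring on constant series), RMSE, the absolute relative
error of totals, and the residual standard error RMSE·√(n/(n−3)) for three
fitted parameters. Noiseless self-generated targets are recovered to 1e-4
per parameter; with 0.2 mm d⁻¹ Gaussian noise over 3650 days, within 5 %.

## Crop coefficients

- Linear: K_c = 1 + (EORATIO − 1)·LAI/6, LAI capped at 6 (the cap applies
  only to this form). EORATIO default 1.1, so K_c ∈ [1.0, 1.1].
- Dynamic: K_c = K_c,min + (K_c,max − K_c,min)(1 − e^{−0.5 LAI}),
  winter-wheat defaults 0.4 and 1.15, evaluated uncapped (its asymptote
  bounds it). At the peak simulated wheat LAI of 7.9 the realized maximum
  is 1.136.

For LAI ≲ 2.1 the dynamic form sits below the linear form — the
early-season overestimation the dynamic model exists to remove. Kc is
evaluated from same-day LAI with no smoothing.

Plans: Plan 1 = PT ET0 with K_c ≡ 1 (so all plans share one code path);
Plan 2 = PT + dynamic Kc; Plan 3 = (calibrated) Hargreaves + dynamic Kc.

## Radiation

d_r = 1 + 0.033 cos(2πJ/D); δ = 0.409 sin(2πJ/D − 1.39);
ω_s = arccos(−tan φ tan δ) with the argument clipped to ±1 so polar day/
night give π/0; R_a = (118.08/π) d_r [ω_s sin φ sin δ + cos φ cos δ sin ω_s],
floored at 0; N = 24 ω_s/π. D is the calendar year's length (365 or 366),
not fixed 365. Angstrom–Prescott R_s = (a_s + b_s n/N) R_a with seasonal
coefficients (spring 0.152/0.556, summer 0.115/0.588, autumn 0.301/0.311,
winter 0.172/0.536; seasons Mar–May, Jun–Aug, Sep–Nov, Dec–Feb). Sunshine
exceeding N is clipped with a warning; at N = 0 only the a_s floor
transmits.

## Soil pedotransfer

θ_s = −0.178 + 0.331 C + 1.538 W − 0.105 C² − 0.409 W² − 0.530 CW (a
fraction), W = 1 − γ_b/ρ. The field-capacity and wilting-point regressions
θ_c = −66.58 + 23.24 ln θ_s and θ_w = −38.75 + 12.53 ln θ_s only produce
physical values with θ_s in percent, so the fraction is converted to
percent between the two steps — the published chain is silent on the unit
switch and the percent reading is the only physically plausible one.
Compositions driving θ_s outside (0, 1) raise a named error. The ordering
θ_w < θ_c < θ_s is verified over clay ∈ [0.05, 0.6] × bulk density
∈ [1.0, 1.7] g cm⁻³.

## Water accounting

Observed ETc = (M1 + P + I + CR) − (M2 + D + R); CR defaults to 0 (deep
water table); negative results are reported, never clamped. Stage windows
are endpoint-inclusive (a 02/06–02/15 stage is 10 days). Effective
precipitation defaults to the USDA-SCS monthly method, P_e = P(125 −
0.2P)/125 for monthly P ≤ 250 mm, else 125 + 0.1P, summed over calendar
months, with a fixed-fraction fallback; the method is configurable because
the seasonal identity IWR + P_eff = ETc is method-agnostic. Seasonal IWR is
the plain difference ETc − P_eff (optionally floored at zero for
daily-scale deficit accounting).

## Synthetic data

The weather generator emulates a temperate continental plain station:
sinusoidal annual temperature (mean 14.1 °C, amplitude 14 °C — northern
Henan normals) with AR(1) anomalies (sd 2 °C, lag-1 0.7); diurnal range
10 °C, narrowed on wet days; two-state precipitation occurrence (annual
mean wet-day probability 0.25) with gamma-distributed depths (mean
6.4 mm → ≈ 580 mm yr⁻¹), both seasonally modulated so rain concentrates in
the warm months while the annual means are preserved (the modulation's
occurrence–depth covariance is normalized out); sunshine as a perturbed
fraction (0.55) of astronomical daylength, reduced under rain; humidity
elevated on wet days; lognormal 2-m wind around 2 m s⁻¹. Outputs are
rounded to the file-format precision so written files round-trip exactly.
Solar radiation is left absent and filled from sunshine via
Angstrom–Prescott downstream, mirroring station practice.

The LAI generator is a deterministic saturating rise to exactly `max_lai`
at `peak_day` followed by exponential senescence — unimodal and
parameter-sparse. It is a stand-in for crop-model canopy output, not a
phenology model: it has no thermal-time control, no winter dormancy
plateau, and no stress response.

What passing tests therefore show: the formulas, their compositions, the
calibration machinery and the accounting identities are implemented
correctly, and the pipeline is deterministic end-to-end. What they do not
show: predictive skill on real stations — the generator has no weather
fronts, no humidity–temperature coupling beyond wet-day shifts, and its
LAI is not driven by the weather it accompanies.

## Numerical choices

- arccos arguments clipped to ±1; Angstrom sunshine clipped to daylength
  with a warning; negative ET0 floored at 0.
- Weather file precision: 0.1 for temperatures, precipitation, sunshine,
  humidity; 0.01 for wind and radiation. DSSAT-style files use −99
  sentinels for absent values; absent values in memory are `None`, never 0.
- Dates are calendar dates; day-of-year is 1-based; DSSAT YYDDD years < 50
  map to 20YY.
- Problem sizes in the test and acceptance runs — a 232-day season,
  3650-day calibration series, 1000-day oracle comparisons — are the
  package's chosen verification scale: large enough for binomial and
  least-squares error bounds to bite, small enough to run in seconds.

## Known limitations

- The Priestley–Taylor EEQ unit quirk described above.
- Only daily records; no sub-daily aggregation rules are defined.
- Deep drainage and runoff are inputs to the water balance, not modelled.
- The USDA-SCS choice for effective precipitation is a convention; where a
  different local method is standard, the seasonal identity still holds but
  the P_eff split differs.
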