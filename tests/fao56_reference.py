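"""Independent FAO-56 daily Penman-Monteith reference (test oracle).

A deliberately self-contained transliteration of the FAO Irrigation and
Drainage Paper 56 daily procedure, written directly from its published
step-by-step boxes and sharing no code with the package implementation.
Used only to cross-check ``wheatwater.et0.et0_penman_monteith``.
"""

import math

GSC = 0.0820  # solar constant, MJ m-2 min-1
SIGMA = 4.903e-9  # Stefan-Boltzmann, MJ K-4 m-2 d-1


def reference_et0(
    doy: int,
    latitude_deg: float,
    elevation_m: float,
    tmax: float,
    tmin: float,
    rh_mean: float,
    u2: float,
    rs: float,
    days_in_year: int = 365,
) -> float:
    tmean = (tmax + tmin) / 2.0

    def e0(t):
        return 0.6108 * math.exp(17.27 * t / (t + 237.3))

    es = (e0(tmax) + e0(tmin)) / 2.0
    ea = min(es, rh_mean / 100.0 * es)
    delta = 4098.0 * e0(tmean) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / days_in_year)
    decl = 0.409 * math.sin(2.0 * math.pi * doy / days_in_year - 1.39)
    x = -math.tan(phi) * math.tan(decl)
    ws = math.acos(max(-1.0, min(1.0, x)))
    ra = (
        24.0 * 60.0 / math.pi * GSC * dr
        * (
            ws * math.sin(phi) * math.sin(decl)
            + math.cos(phi) * math.cos(decl) * math.sin(ws)
        )
    )
    ra = max(0.0, ra)
    rso = (0.75 + 2e-5 * elevation_m) * ra
    rns = 0.77 * rs
    ratio = min(rs / rso, 1.0) if rso > 0 else 1.0
    rnl = (
        SIGMA
        * (((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0)
        * (0.34 - 0.14 * math.sqrt(ea))
        * (1.35 * ratio - 0.35)
    )
    rn = rns - rnl

    num = 0.408 * delta * rn + gamma * 900.0 / (tmean + 273.0) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return max(0.0, num / den)
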