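"""Pedotransfer functions: soil hydraulic constants from composition.

Saturated water content follows a quadratic regression in clay fraction C
and total porosity W = 1 - gamma/rho (bulk over particle density); field
capacity and wilting point follow logarithmic regressions in the saturated
content *expressed in percent* — the published coefficients only produce
physical values on that scale, so the fraction from the first regression is
converted to percent before the log forms are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SoilLayerComposition", "SoilHydraulics", "porosity", "pedotransfer"]


@dataclass(frozen=True)
class SoilLayerComposition:
    """Composition of one soil layer: clay fraction (0-1), bulk density and
    particle (specific) gravity in g cm-3 (default 2.65, quartz-dominated
    mineral soil)."""

    clay_fraction: float
    bulk_density: float
    specific_gravity: float = 2.65

    def __post_init__(self) -> None:
        if not 0.0 <= self.clay_fraction <= 1.0:
            raise ValueError("clay_fraction must be in [0, 1]")
        if not 0.0 < self.bulk_density < self.specific_gravity:
            raise ValueError(
                "bulk_density must be positive and below specific_gravity"
            )


@dataclass(frozen=True)
class SoilHydraulics:
    """Volumetric water contents in percent: saturation, field capacity,
    wilting point; always ordered theta_wp < theta_fc < theta_s."""

    theta_s: float
    theta_fc: float
    theta_wp: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_wp < self.theta_fc < self.theta_s <= 100.0:
            raise ValueError(
                "require 0 < wilting < field capacity < saturation <= 100 "
                f"(got {self.theta_wp:.2f}, {self.theta_fc:.2f}, "
                f"{self.theta_s:.2f})"
            )


def porosity(composition: SoilLayerComposition) -> float:
    """Total porosity W = 1 - bulk_density / specific_gravity (0-1)."""
    return 1.0 - composition.bulk_density / composition.specific_gravity


def saturated_water_content(composition: SoilLayerComposition) -> float:
    """Saturated volumetric water content as a fraction (0-1)."""
    c = composition.clay_fraction
    w = porosity(composition)
    theta_s = (
        -0.178 + 0.331 * c + 1.538 * w - 0.105 * c**2 - 0.409 * w**2 - 0.530 * c * w
    )
    if not 0.0 < theta_s < 1.0:
        raise ValueError(
            f"composition (clay={c}, bulk_density={composition.bulk_density}) "
            f"yields non-physical saturated content {theta_s:.3f}"
        )
    return theta_s


def pedotransfer(composition: SoilLayerComposition) -> SoilHydraulics:
    """Map composition to (saturation, field capacity, wilting point), all
    percent volumetric.

    theta_fc = -66.58 + 23.24 ln(theta_s%)
    theta_wp = -38.75 + 12.53 ln(theta_s%)
    """
    theta_s_pct = 100.0 * saturated_water_content(composition)
    log_ts = math.log(theta_s_pct)
    theta_fc = -66.58 + 23.24 * log_ts
    theta_wp = -38.75 + 12.53 * log_ts
    return SoilHydraulics(theta_s=theta_s_pct, theta_fc=theta_fc, theta_wp=theta_wp)
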