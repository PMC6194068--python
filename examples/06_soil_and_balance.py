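"""Soil hydraulic constants and observed ETc from a field water balance.

The pedotransfer maps (clay fraction, bulk density) to saturation, field
capacity and wilting point; the water balance converts soil-moisture and
flux measurements into observed crop evapotranspiration for one stage.
"""

from wheatwater import (
    SoilLayerComposition,
    WaterBalanceComponents,
    observed_etc,
    pedotransfer,
    porosity,
)

topsoil = SoilLayerComposition(clay_fraction=0.30, bulk_density=1.325)
hyd = pedotransfer(topsoil)
print(f"porosity          {porosity(topsoil):.3f}")
print(f"saturation        {hyd.theta_s:.2f} %vol")
print(f"field capacity    {hyd.theta_fc:.2f} %vol")
print(f"wilting point     {hyd.theta_wp:.2f} %vol")

# one jointing-stage window: profile drawdown plus rain and irrigation;
# capillary rise is negligible with a deep water table
stage = WaterBalanceComponents(
    m1_initial_soil_moisture=310.0,
    m2_final_soil_moisture=285.0,
    precipitation=18.0,
    irrigation=60.0,
    capillary_rise=0.0,
    deep_drainage=5.0,
    runoff=0.0,
)
print(f"\nobserved stage ETc: {observed_etc(stage):.1f} mm")
# = (310 + 18 + 60 + 0) - (285 + 5 + 0): water in minus water left/lost.
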