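import datetime as dt
import itertools

import numpy as np
import pytest

from wheatwater import (
    StageDefinition,
    WaterBalanceComponents,
    aggregate_stages,
    effective_precipitation,
    irrigation_water_requirement,
    observed_etc,
)

D = dt.date

# Published seasonal ETc / effective-precipitation pairs (mm/a) for the two
# forcing scenarios and three future periods; IWR must equal their
# difference exactly.
SCENARIO_TABLE = [
    ("rcp45_2020s", 441.89, 195.02, 246.87),
    ("rcp45_2050s", 445.10, 200.15, 244.95),
    ("rcp45_2080s", 449.24, 208.27, 240.97),
    ("rcp85_2020s", 438.81, 194.19, 244.62),
    ("rcp85_2050s", 442.56, 184.15, 258.41),
    ("rcp85_2080s", 429.47, 191.58, 237.89),
]


class TestObservedEtc:
    def test_simple_balance(self):
        c = WaterBalanceComponents(300.0, 300.0, 20.0, 50.0)
        assert observed_etc(c) == pytest.approx(70.0)

    def test_all_zero(self):
        assert observed_etc(WaterBalanceComponents(0, 0, 0, 0)) == 0.0

    def test_matches_sum_of_terms_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            v = rng.uniform(0, 400, size=7)
            c = WaterBalanceComponents(*v)
            assert observed_etc(c) == pytest.approx(
                v[0] + v[2] + v[3] + v[4] - v[1] - v[5] - v[6], rel=1e-12
            )

    def test_permutation_invariance_within_groups(self):
        # swapping members of the additive group (P <-> I) or the
        # subtractive group (D <-> R) leaves ETc unchanged
        a = WaterBalanceComponents(300, 250, 20, 50, 5, 8, 3)
        b = WaterBalanceComponents(300, 250, 50, 20, 5, 3, 8)
        assert observed_etc(a) == pytest.approx(observed_etc(b))

    def test_may_be_negative_never_clamped(self):
        c = WaterBalanceComponents(100.0, 300.0, 0.0, 0.0)
        assert observed_etc(c) == -200.0

    def test_negative_components_rejected(self):
        with pytest.raises(ValueError):
            WaterBalanceComponents(-1.0, 0, 0, 0)


def _constant_series(start: dt.date, n: int, value: float = 1.0):
    return {start + dt.timedelta(days=k): value for k in range(n)}


class TestStageAggregation:
    def test_one_day_stage(self):
        series = _constant_series(D(2016, 2, 1), 30, 2.5)
        stage = StageDefinition("day", D(2016, 2, 10), D(2016, 2, 10))
        assert aggregate_stages(series, [stage])["day"] == pytest.approx(2.5)

    def test_overwintering_stage_window_inclusive(self):
        # the 02/06-02/15 window spans ten days endpoint-inclusive
        series = _constant_series(D(2016, 1, 1), 60, 1.0)
        stage = StageDefinition("Stage 2", D(2016, 2, 6), D(2016, 2, 15))
        assert stage.n_days == 10
        assert aggregate_stages(series, [stage])["Stage 2"] == pytest.approx(10.0)

    def test_partition_sums_to_whole_season(self):
        rng = np.random.default_rng(3)
        start = D(2015, 10, 18)
        series = {
            start + dt.timedelta(days=k): float(v)
            for k, v in enumerate(rng.uniform(0, 6, size=120))
        }
        cuts = [0, 30, 55, 80, 120]
        stages = [
            StageDefinition(
                f"s{i}",
                start + dt.timedelta(days=a),
                start + dt.timedelta(days=b - 1),
            )
            for i, (a, b) in enumerate(itertools.pairwise(cuts))
        ]
        whole = StageDefinition("whole", start, start + dt.timedelta(days=119))
        totals = aggregate_stages(series, stages + [whole])
        assert sum(totals[f"s{i}"] for i in range(4)) == pytest.approx(
            totals["whole"], rel=1e-12
        )
        assert totals["whole"] == pytest.approx(sum(series.values()), rel=1e-12)

    def test_stage_outside_span_rejected(self):
        series = _constant_series(D(2016, 2, 1), 10)
        stage = StageDefinition("late", D(2016, 3, 1), D(2016, 3, 5))
        with pytest.raises(ValueError, match="outside"):
            aggregate_stages(series, [stage])

    def test_inverted_stage_rejected(self):
        with pytest.raises(ValueError):
            StageDefinition("bad", D(2016, 3, 5), D(2016, 3, 1))


class TestEffectivePrecipitation:
    def test_zero_rain_gives_zero(self):
        series = _constant_series(D(2016, 3, 1), 31, 0.0)
        assert effective_precipitation(series, "usda_scs") == 0.0
        assert effective_precipitation(series, "fixed_fraction") == 0.0

    def test_fixed_fraction(self):
        series = _constant_series(D(2016, 3, 1), 10, 10.0)  # 100 mm
        assert effective_precipitation(
            series, "fixed_fraction", fraction=0.8
        ) == pytest.approx(80.0)

    def test_usda_scs_monthly_matches_hand_computation(self):
        # 100 mm in one calendar month: Pe = 100*(125 - 20)/125 = 84 mm
        march = _constant_series(D(2016, 3, 1), 20, 5.0)
        assert effective_precipitation(march, "usda_scs") == pytest.approx(84.0)
        # 300 mm in one month crosses the 250 mm branch: Pe = 125 + 30
        wet = _constant_series(D(2016, 7, 1), 30, 10.0)
        assert effective_precipitation(wet, "usda_scs") == pytest.approx(155.0)

    def test_usda_scs_sums_over_months(self):
        two_months = {
            **_constant_series(D(2016, 3, 1), 20, 5.0),   # 100 mm in March
            **_constant_series(D(2016, 4, 1), 10, 5.0),   # 50 mm in April
        }
        expected = 84.0 + 50.0 * (125 - 0.2 * 50) / 125
        assert effective_precipitation(two_months, "usda_scs") == pytest.approx(
            expected
        )

    def test_never_exceeds_total_precipitation(self):
        rng = np.random.default_rng(12)
        start = D(2015, 10, 1)
        series = {
            start + dt.timedelta(days=k): float(p)
            for k, p in enumerate(rng.gamma(0.5, 8.0, size=240))
        }
        total = sum(series.values())
        for method in ("usda_scs", "fixed_fraction"):
            peff = effective_precipitation(series, method)
            assert 0.0 <= peff <= total

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            effective_precipitation(_constant_series(D(2016, 3, 1), 5), "magic")


class TestIrrigationWaterRequirement:
    @pytest.mark.parametrize("label,etc,peff,iwr", SCENARIO_TABLE)
    def test_scenario_identity_to_001mm(self, label, etc, peff, iwr):
        assert irrigation_water_requirement(etc, peff) == pytest.approx(
            iwr, abs=0.005
        )

    def test_fully_met_by_rain(self):
        assert irrigation_water_requirement(300.0, 300.0) == 0.0

    def test_surplus_not_floored_by_default(self):
        assert irrigation_water_requirement(200.0, 250.0) == -50.0

    def test_daily_deficit_flooring_option(self):
        assert irrigation_water_requirement(200.0, 250.0, floor_at_zero=True) == 0.0
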