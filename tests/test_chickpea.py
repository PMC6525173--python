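import datetime as dt
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoflow.phenology_chickpea import (
    CHICKPEA_CULTIVARS,
    CardinalTemps,
    ChickpeaCultivarParams,
    Stage,
    SWModificationParams,
    advance_stage,
    daily_thermal_time,
    get_chickpea_cultivar,
    modify_tt,
    phase_target,
    simulate_chickpea,
)
from phenoflow.scenarios import build_fixture_soils

from conftest import make_constant_weather, make_two_layer_profile


def flat_pp_cultivar(**overrides):
    """Cultivar with a photoperiod-independent endjuv->init target."""
    defaults = dict(
        name="test",
        pp_knots=(1.0, 24.0),
        tt_endjuv_to_init_at_knots=(0.0, 0.0),
        tt_emerg_to_endjuv=660.0,
        tt_init_to_flower=33.0,
    )
    defaults.update(overrides)
    return ChickpeaCultivarParams(**defaults)


class TestDailyThermalTime:
    def test_mean_below_optimum_equals_mean(self):
        # mean 15 C -> 15 Cd
        assert daily_thermal_time(20.0, 10.0) == pytest.approx(15.0)

    def test_zero_at_ceiling(self):
        assert daily_thermal_time(45.0, 35.0) == 0.0

    def test_decline_between_optimum_and_ceiling(self):
        # mean 35 C: halfway down the 30 -> 40 decline from 30 Cd
        assert daily_thermal_time(40.0, 30.0) == pytest.approx(15.0)

    def test_zero_at_or_below_base(self):
        assert daily_thermal_time(2.0, -2.0) == 0.0
        assert daily_thermal_time(0.0, -10.0) == 0.0

    def test_maximum_at_optimum(self):
        assert daily_thermal_time(30.0, 30.0) == pytest.approx(30.0)

    def test_custom_cardinals(self):
        c = CardinalTemps(base=5.0, optimum=25.0, ceiling=35.0)
        assert daily_thermal_time(25.0, 15.0, c) == pytest.approx(15.0)

    def test_cardinal_ordering_enforced(self):
        with pytest.raises(ValueError):
            CardinalTemps(base=30.0, optimum=30.0, ceiling=40.0)

    def test_tmax_ge_tmin_required(self):
        with pytest.raises(ValueError):
            daily_thermal_time(5.0, 10.0)

    @given(m=st.floats(min_value=-10.0, max_value=60.0))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_nonnegative(self, m):
        tt = daily_thermal_time(m, m)
        assert 0.0 <= tt <= 30.0


class TestPhaseTarget:
    def test_original_at_lower_knot(self):
        cv = get_chickpea_cultivar("hattrick", "original")
        assert phase_target(
            10.7, cv.pp_knots, cv.tt_endjuv_to_init_at_knots
        ) == pytest.approx(446.0)

    def test_original_at_upper_knot(self):
        cv = get_chickpea_cultivar("hattrick", "original")
        assert phase_target(
            17.0, cv.pp_knots, cv.tt_endjuv_to_init_at_knots
        ) == pytest.approx(0.0)

    def test_new_model_flat_beyond_12h(self):
        cv = get_chickpea_cultivar("hattrick", "soilwater")
        assert cv.pp_knots == (10.7, 12.0)
        assert phase_target(
            13.0, cv.pp_knots, cv.tt_endjuv_to_init_at_knots
        ) == pytest.approx(0.0)

    def test_flat_below_first_knot(self):
        cv = get_chickpea_cultivar("hattrick", "original")
        assert phase_target(
            9.0, cv.pp_knots, cv.tt_endjuv_to_init_at_knots
        ) == pytest.approx(446.0)

    def test_midpoint_interpolation(self):
        assert phase_target(
            (10.7 + 17.0) / 2, (10.7, 17.0), (446.0, 0.0)
        ) == pytest.approx(223.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            phase_target(12.0, (10.0, 12.0, 14.0), (400.0, 0.0))

    def test_tyson_parameters(self):
        cv = get_chickpea_cultivar("tyson", "original")
        assert cv.pp_knots[0] == 10.1
        assert cv.tt_endjuv_to_init_at_knots[0] == pytest.approx(468.3)
        assert CHICKPEA_CULTIVARS["tyson"]["soilwater"].tt_emerg_to_endjuv == 690.0


class TestModifyTT:
    def test_multiplier_is_one_at_threshold(self):
        p = SWModificationParams()
        assert modify_tt(20.0, 0.65, int(Stage.EMERGENCE), p) == pytest.approx(
            20.0
        )

    @pytest.mark.parametrize("fasw", [1.0, 1.2])
    def test_full_wetness_multiplier(self, fasw):
        # 20 * (1.65 - 1) = 13, supersaturation clamps at 1
        p = SWModificationParams()
        assert modify_tt(20.0, fasw, int(Stage.EMERGENCE), p) == pytest.approx(
            13.0
        )

    def test_gate_closed_below_threshold(self):
        p = SWModificationParams()
        assert modify_tt(20.0, 0.5, int(Stage.EMERGENCE), p) == 20.0

    def test_gate_closed_before_emergence(self):
        p = SWModificationParams()
        assert modify_tt(20.0, 0.9, int(Stage.GERMINATION), p) == 20.0

    def test_gate_closed_after_flowering(self):
        p = SWModificationParams()
        assert modify_tt(20.0, 0.9, int(Stage.FLOWERING), p) == 20.0

    @given(
        tt=st.floats(min_value=0.0, max_value=30.0),
        fasw=st.floats(min_value=0.0, max_value=1.3),
        stage=st.integers(min_value=1, max_value=10),
    )
    @settings(max_examples=200, deadline=None)
    def test_never_exceeds_tt_and_multiplier_bounds(self, tt, fasw, stage):
        p = SWModificationParams()
        ttm = modify_tt(tt, fasw, stage, p)
        assert ttm <= tt + 1e-12
        if tt > 0:
            assert 0.65 - 1e-12 <= ttm / tt <= 1.0 + 1e-12

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SWModificationParams(threshold=0.0)
        with pytest.raises(ValueError):
            SWModificationParams(constant=0.5, threshold=0.65)


class TestAdvanceStage:
    def test_carry_over(self):
        targets = {4: 450.0, 5: 100.0}
        stage, cum = advance_stage(4, 449.0, 2.0, targets.__getitem__)
        assert stage == 5
        assert cum == pytest.approx(1.0)

    def test_zero_day_no_change(self):
        targets = {4: 450.0}
        stage, cum = advance_stage(4, 10.0, 0.0, targets.__getitem__)
        assert (stage, cum) == (4, 10.0)

    def test_zero_target_passes_through(self):
        targets = {4: 0.0, 5: 50.0}
        stage, cum = advance_stage(4, 0.0, 5.0, targets.__getitem__)
        assert stage == 5
        assert cum == pytest.approx(5.0)


class TestSimulateChickpea:
    def test_closed_form_flowering_day(self):
        """Constant 10 Cd/day against the division oracle.

        Phase chain to flowering {90, 660, 0, 33} = 783 Cd; germination
        takes day 1, accumulation starts day 2, so flowering falls on
        day ceil(783/10) + 1 = 80 from sowing.
        """
        weather = make_constant_weather(tmax=15.0, tmin=5.0)
        profile = make_two_layer_profile()
        cv = flat_pp_cultivar()
        trace = simulate_chickpea(
            weather,
            profile,
            cv,
            sowing_date=weather.start,
            sw_params=None,
            starting_water=0.5,
        )
        assert trace.flowered
        assert trace.days_to_flowering == math.ceil(783 / 10) + 1 == 80

    def test_dry_scenario_modification_is_noop(self):
        weather = make_constant_weather(rain=0.0)
        profile = make_two_layer_profile()
        cv = flat_pp_cultivar()
        kw = dict(
            sowing_date=weather.start, starting_water=0.4
        )  # FASW starts at 0.4 < 0.65 and only declines
        with_mod = simulate_chickpea(
            weather, profile, cv, sw_params=SWModificationParams(), **kw
        )
        without = simulate_chickpea(weather, profile, cv, sw_params=None, **kw)
        assert with_mod.days_to_flowering == without.days_to_flowering

    def test_wet_scenario_delays_flowering(self):
        weather = make_constant_weather(rain=25.0)
        profile = make_two_layer_profile()
        cv = flat_pp_cultivar()
        kw = dict(sowing_date=weather.start, starting_water=1.0)
        with_mod = simulate_chickpea(
            weather, profile, cv, sw_params=SWModificationParams(), **kw
        )
        without = simulate_chickpea(weather, profile, cv, sw_params=None, **kw)
        assert with_mod.days_to_flowering > without.days_to_flowering

    def test_constant_saturation_delay_factor(self):
        """Daily heavy rain holds FASW >= 1, so the gated phases run at a
        constant 0.65 multiplier: 9 accrual days to emergence (90 Cd at
        10 Cd/day), then ceil(693 / 6.5) = 107 days to flowering."""
        weather = make_constant_weather(tmax=15.0, tmin=5.0, rain=25.0)
        profile = make_two_layer_profile()
        cv = flat_pp_cultivar()
        trace = simulate_chickpea(
            weather,
            profile,
            cv,
            sowing_date=weather.start,
            sw_params=SWModificationParams(),
            starting_water=1.0,
        )
        assert trace.flowered
        assert trace.days_to_flowering == 1 + 9 + math.ceil(693 / 6.5)

    def test_ttm_never_exceeds_tt(self):
        weather = make_constant_weather(rain=10.0)
        profile = make_two_layer_profile()
        cv = flat_pp_cultivar()
        trace = simulate_chickpea(
            weather,
            profile,
            cv,
            sowing_date=weather.start,
            sw_params=SWModificationParams(),
            starting_water=0.9,
        )
        for tt, ttm in zip(trace.tt, trace.ttm):
            assert ttm <= tt + 1e-12

    def test_stage_codes_non_decreasing(self):
        weather = make_constant_weather(rain=5.0)
        profile = make_two_layer_profile()
        cv = flat_pp_cultivar()
        trace = simulate_chickpea(
            weather,
            profile,
            cv,
            sowing_date=weather.start,
            sw_params=SWModificationParams(),
            starting_water=0.8,
        )
        assert all(b >= a for a, b in zip(trace.stages, trace.stages[1:]))

    def test_did_not_flower_is_not_an_error(self):
        weather = make_constant_weather(n_days=10)
        profile = make_two_layer_profile()
        cv = flat_pp_cultivar()
        trace = simulate_chickpea(
            weather, profile, cv, sowing_date=weather.start, sw_params=None
        )
        assert not trace.flowered
        assert trace.days_to_flowering is None

    def test_sowing_outside_weather(self):
        weather = make_constant_weather(n_days=10)
        profile = make_two_layer_profile()
        with pytest.raises(ValueError):
            simulate_chickpea(
                weather,
                profile,
                flat_pp_cultivar(),
                sowing_date=weather.end + dt.timedelta(days=1),
            )

    def test_wider_pp_range_never_hastens_winter_sowing(self):
        """Raising the upper knot from 12 h to 17 h raises the phase
        target at every winter (sub-12 h) photoperiod, so flowering with
        the 17 h knot is never earlier than with the 12 h knot."""
        soils = build_fixture_soils()
        from phenoflow.weather import generate_synthetic_weather

        weather = generate_synthetic_weather(
            -28.2, dt.date(2015, 1, 1), 365, seed=21
        )
        kw = dict(
            sowing_date=dt.date(2015, 5, 15),
            sw_params=None,
            starting_water=0.7,
        )
        narrow = simulate_chickpea(
            weather,
            soils["vertisol_136"],
            ChickpeaCultivarParams(
                name="n",
                pp_knots=(10.7, 12.0),
                tt_endjuv_to_init_at_knots=(446.0, 0.0),
                tt_emerg_to_endjuv=660.0,
            ),
            **kw,
        )
        wide = simulate_chickpea(
            weather,
            soils["vertisol_136"],
            ChickpeaCultivarParams(
                name="w",
                pp_knots=(10.7, 17.0),
                tt_endjuv_to_init_at_knots=(446.0, 0.0),
                tt_emerg_to_endjuv=660.0,
            ),
            **kw,
        )
        assert wide.days_to_flowering >= narrow.days_to_flowering

    def test_trace_dataframe_and_summary(self):
        weather = make_constant_weather()
        profile = make_two_layer_profile()
        trace = simulate_chickpea(
            weather,
            profile,
            flat_pp_cultivar(),
            sowing_date=weather.start,
            sw_params=None,
        )
        df = trace.to_dataframe()
        assert set(df.columns) >= {
            "date",
            "stage",
            "tt",
            "ttm",
            "fasw",
            "daylength",
        }
        s = trace.summary()
        assert s["flowered"]
        assert s["days_to_flowering"] == trace.days_to_flowering
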