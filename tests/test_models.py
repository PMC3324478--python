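import datetime as dt

import numpy as np
import pytest

from phenoleaf import (
    AMParams,
    GSIParams,
    PMParams,
    SMParams,
    StartDateSpec,
    SWParams,
    TPParams,
    predict,
    predict_am,
    predict_gsi,
    predict_pm,
    predict_sm,
    predict_sw,
    predict_tp,
)
from phenoleaf.errors import CoverageError, InvalidParameterError
from phenoleaf.models import chilling_triangular, forcing_gdd, forcing_sigmoid

from conftest import (
    add_precip,
    constant_series,
    random_params,
    series_from_arrays,
    shift_temperature,
)

JAN1 = StartDateSpec.jan1()


class TestRateFunctions:
    @pytest.mark.parametrize(
        "tmean,tb,expected", [(10.0, 0.0, 10.0), (-5.0, 0.0, 0.0), (7.4, 7.4, 0.0)]
    )
    def test_degree_day_forcing(self, tmean, tb, expected):
        assert forcing_gdd(tmean, tb) == expected

    def test_sigmoid_midpoint_is_half_asymptote(self):
        assert forcing_sigmoid(18.4, 28.4, -0.185, -18.4) == pytest.approx(14.2)

    def test_sigmoid_upper_asymptote(self):
        assert forcing_sigmoid(1e3, 28.4, -0.185, -18.4) == pytest.approx(28.4)

    def test_sigmoid_matches_direct_evaluation_at_zero(self):
        expected = 28.4 / (1.0 + np.exp(-0.185 * (0.0 - 18.4)))
        assert forcing_sigmoid(0.0, 28.4, -0.185, -18.4) == pytest.approx(expected)

    def test_triangular_chilling_shape(self):
        lo, opt, hi = -3.4, 3.5, 10.4
        assert chilling_triangular(opt, lo, opt, hi) == 1.0
        assert chilling_triangular(lo, lo, opt, hi) == 0.0
        assert chilling_triangular(hi, lo, opt, hi) == 0.0
        assert chilling_triangular((lo + opt) / 2, lo, opt, hi) == pytest.approx(0.5)
        assert chilling_triangular(-20.0, lo, opt, hi) == 0.0


class TestClosedFormToys:
    def test_sw_constant_warmth_tenth_day(self):
        series = constant_series(10.0)
        pred = predict_sw(series, SWParams(T_b=0.0, F_star=100.0, t0=JAN1), 2001)
        assert pred.leafing_doy == 10

    def test_sw_zero_requirement_leafs_at_start(self):
        series = constant_series(10.0)
        pred = predict_sw(series, SWParams(T_b=0.0, F_star=0.0, t0=JAN1), 2001)
        assert pred.leafing_doy == 1

    def test_tp_binding_hydro_threshold_tenth_day(self):
        # previous year precip sums to 100 mm; current year 2 mm/day
        n_prev = 366  # 2000 is a leap year
        precip = np.concatenate([np.full(n_prev, 100.0 / n_prev), np.full(365, 2.0)])
        series = series_from_arrays(10.0, precip)
        params = TPParams(T_b=0.0, F_star=50.0, k1=0.1, k2=1.0, P_crit=30.0, t0=JAN1)
        pred = predict_tp(series, params, 2001)
        # thermal met on day 5 (10 deg C day/day); hydro 10 + 2i >= 30 on day 10
        assert pred.leafing_doy == 10
        assert pred.reached_thermal and pred.reached_hydro

    def test_sm_two_days_of_forcing_after_quiescence(self):
        t_o = 3.5
        tmean = np.concatenate([np.full(10, t_o), np.full(721, 18.4)])
        series = series_from_arrays(tmean, 0.0)
        params = SMParams(T_b=0.0, C_star=10.0, F_star=28.4, T_o=t_o, t0=JAN1)
        pred = predict_sm(series, params, 2000)
        # chilling at 1 CU/day -> t1 on day 10; 14.2 FU/day at 18.4 deg C
        assert pred.leafing_doy == 12

    def test_sm_zero_chilling_requirement_is_pure_forcing(self):
        series = constant_series(18.4)
        params = SMParams(T_b=0.0, C_star=0.0, F_star=28.4, T_o=3.5, t0=JAN1)
        assert predict_sm(series, params, 2001).leafing_doy == 2

    def test_am_moving_target_fourth_warm_day(self):
        tmean = np.concatenate([np.full(10, 0.0), np.full(721, 15.0)])
        series = series_from_arrays(tmean, 0.0)
        params = AMParams(T_b=5.0, C_star=0.0, a=100.0, b=-0.1, t0=JAN1)
        pred = predict_am(series, params, 2000)
        # 10 chill days relax the target to 100 e^-1 = 36.8 deg C day;
        # at 10 deg C day per warm day the 4th warm day crosses it
        assert pred.leafing_doy == 14

    def test_am_zero_rate_reduces_to_fixed_requirement(self):
        series = constant_series(10.0)
        am = predict_am(series, AMParams(T_b=0.0, C_star=0.0, a=100.0, b=0.0, t0=JAN1), 2001)
        sw = predict_sw(series, SWParams(T_b=0.0, F_star=100.0, t0=JAN1), 2001)
        assert am.leafing_doy == sw.leafing_doy == 10

    def test_pm_unchilled_buds_fully_competent_at_km_one(self):
        series = constant_series(18.4)
        pred = predict_pm(
            series, PMParams(C_star=50.0, F_star=28.4, K_m=1.0, T_o=3.5, t0=JAN1), 2001
        )
        assert pred.leafing_doy == 2

    def test_pm_no_chilling_no_competence_never_leafs(self):
        series = constant_series(20.0)  # always above T_high: zero chilling
        pred = predict_pm(
            series, PMParams(C_star=10.0, F_star=50.0, K_m=0.0, T_o=3.5, t0=JAN1), 2001
        )
        assert pred.leafing_doy is None and not pred.reached

    def test_gsi_saturating_conditions_leafs_day_one(self):
        series = constant_series(20.0, rh=100.0, tmin_offset=5.0, latitude=0.0)
        pred = predict_gsi(series, GSIParams(), 2001)
        assert pred.leafing_doy == 1

    def test_gsi_cold_minimum_never_leafs(self):
        series = constant_series(0.0, rh=70.0, tmin_offset=5.0, latitude=0.0)
        # tmin = -5 deg C, below the -2 deg C ramp foot -> indicator 0
        pred = predict_gsi(series, GSIParams(), 2001)
        assert pred.leafing_doy is None

    def test_gsi_running_mean_crossing_matches_rolling_oracle(self, monsoon_series):
        from oracles import oracle_gsi

        params = GSIParams(threshold=0.3, window=15)
        mine = predict_gsi(monsoon_series, params, 2001).leafing_doy
        theirs = oracle_gsi(
            list(monsoon_series.records()), monsoon_series.latitude, params, 2001
        )
        assert mine == theirs is not None


class TestReductions:
    def test_tp_without_water_terms_equals_sw(self, random_cases):
        rng = np.random.default_rng(7)
        for series, _ in random_cases:
            sw = random_params("SW", rng)
            tp = TPParams(T_b=sw.T_b, F_star=sw.F_star, k1=0.0, k2=0.0, P_crit=0.0, t0=sw.t0)
            assert (
                predict_tp(series, tp, 2001).leafing_doy
                == predict_sw(series, sw, 2001).leafing_doy
            )

    def test_pm_with_full_competence_ignores_chilling_parameters(self, random_cases):
        rng = np.random.default_rng(8)
        for series, _ in random_cases[:30]:
            base = random_params("PM", rng)
            a = PMParams(C_star=base.C_star, F_star=base.F_star, K_m=1.0,
                         T_o=base.T_o, t0=base.t0)
            b = PMParams(C_star=base.C_star * 2 + 1, F_star=base.F_star, K_m=1.0,
                         T_o=min(base.T_o + 1, 10.0), t0=base.t0)
            assert predict_pm(series, a, 2001).leafing_doy == predict_pm(series, b, 2001).leafing_doy


class TestMonotonicity:
    def test_warming_never_delays_thermal_models(self, random_cases):
        # AM is only monotone in its chilling-free sub-family: warming
        # removes chill days, which both postpones meeting C_star and (for
        # b < 0) raises the forcing requirement a*exp(b*S_c), so a uniform
        # warm shift can legitimately delay AM leafing. Restrict the AM
        # branch to C_star = 0, b >= 0 where the claim holds.
        import dataclasses

        rng = np.random.default_rng(9)
        for model, pred_fn in (("SW", predict_sw), ("TP", predict_tp), ("AM", predict_am)):
            for series, _ in random_cases:
                params = random_params(model, rng)
                if model == "AM":
                    params = dataclasses.replace(params, b=abs(params.b), C_star=0.0)
                base = pred_fn(series, params, 2001).leafing_doy
                warm = pred_fn(shift_temperature(series, 2.0), params, 2001).leafing_doy
                if base is not None:
                    assert warm is not None and warm <= base

    def test_added_precipitation_never_delays_tp(self, random_cases):
        rng = np.random.default_rng(10)
        for series, _ in random_cases[:30]:
            params = random_params("TP", rng)
            base = predict_tp(series, params, 2001).leafing_doy
            wetter = add_precip(series, dt.date(2001, 3, 1), 20.0)
            wet = predict_tp(wetter, params, 2001).leafing_doy
            if base is not None:
                assert wet is not None and wet <= base

    def test_raising_water_threshold_never_advances_tp(self, random_cases):
        rng = np.random.default_rng(11)
        for series, _ in random_cases[:30]:
            params = random_params("TP", rng)
            import dataclasses

            stricter = dataclasses.replace(params, P_crit=params.P_crit + 15.0)
            base = predict_tp(series, params, 2001).leafing_doy
            strict = predict_tp(series, stricter, 2001).leafing_doy
            if strict is not None:
                assert base is not None and base <= strict


class TestThresholdSemantics:
    def test_accumulated_state_straddles_threshold_at_leafing(self, random_cases):
        rng = np.random.default_rng(12)
        for series, records in random_cases[:20]:
            params = random_params("SW", rng)
            doy = predict_sw(series, params, 2001).leafing_doy
            if doy is None or doy <= 1:
                continue
            start = params.t0.resolve(2001)
            upto_prev = sum(
                max(0.0, r.tmean - params.T_b)
                for r in records
                if start <= r.date <= dt.date(2001, 1, 1) + dt.timedelta(days=doy - 2)
            )
            upto_leaf = upto_prev + sum(
                max(0.0, r.tmean - params.T_b)
                for r in records
                if r.date == dt.date(2001, 1, 1) + dt.timedelta(days=doy - 1)
            )
            assert upto_prev < params.F_star <= upto_leaf


class TestContracts:
    def test_predictions_are_deterministic(self, monsoon_series):
        params = TPParams(T_b=5.0, F_star=120.0, k1=0.05, k2=0.5, P_crit=20.0)
        a = predict(monsoon_series, params, 2001)
        b = predict(monsoon_series, params, 2001)
        assert a == b

    def test_missing_previous_year_rejected_for_tp(self, monsoon_series):
        params = TPParams(T_b=5.0, F_star=120.0, k1=0.05, k2=0.5, P_crit=20.0)
        with pytest.raises(CoverageError):
            predict_tp(monsoon_series, params, 2000)

    def test_invalid_parameter_combinations_rejected(self):
        with pytest.raises(InvalidParameterError):
            SMParams(T_b=0.0, C_star=10.0, F_star=100.0, T_o=12.0)  # T_o > T_high
        with pytest.raises(InvalidParameterError):
            PMParams(C_star=10.0, F_star=100.0, K_m=1.5, T_o=3.5)
        with pytest.raises(InvalidParameterError):
            AMParams(T_b=5.0, C_star=10.0, a=0.0, b=0.0)
        with pytest.raises(InvalidParameterError):
            GSIParams(threshold=0.0)
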