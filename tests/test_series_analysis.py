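import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropheight import (
    CorrectionError,
    DailyRecord,
    HeightSeries,
    classify_light,
    compare_features_t,
    flag_unreliable,
    interpolate_flagged,
    load_reference_errors,
    load_reference_table,
    relative_error,
    summarize_errors,
)


def _series(values, flags, start=dt.date(2012, 7, 1), step_days=1):
    records = tuple(
        DailyRecord(
            date=start + dt.timedelta(days=i * step_days),
            estimated_cm=v,
            rain_mmh=0.0,
            flagged=f,
        )
        for i, (v, f) in enumerate(zip(values, flags))
    )
    return HeightSeries(records=records)


class TestRelativeError:
    @pytest.mark.parametrize(
        "est,ref,expected",
        [(159.6, 117.0, 36.41), (77.0, 77.0, 0.00), (50.0, 100.0, 50.0)],
    )
    def test_examples(self, est, ref, expected):
        assert relative_error(est, ref) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_reference_rejected(self):
        for ref in (0.0, -5.0):
            with pytest.raises(ValueError):
                relative_error(10.0, ref)

    @given(
        est=st.floats(0, 500),
        ref=st.floats(1, 500),
        k=st.floats(0.01, 100),
    )
    @settings(max_examples=40, derandomize=True)
    def test_scale_invariance(self, est, ref, k):
        assert relative_error(k * est, k * ref) == pytest.approx(
            relative_error(est, ref), rel=1e-9, abs=1e-9
        )


class TestClassifyLight:
    @pytest.mark.parametrize(
        "light,expected",
        [
            (399.0, "darkness"),
            (400.0, "normal"),  # boundary belongs to the normal band
            (700.0, "normal"),
            (1000.0, "normal"),
            (1000.1, "brightness"),
            (1500.0, "brightness"),
            (0.0, "darkness"),
        ],
    )
    def test_boundaries(self, light, expected):
        assert classify_light(light) == expected

    def test_negative_light_rejected(self):
        with pytest.raises(ValueError):
            classify_light(-1.0)


class TestFlagUnreliable:
    def test_rain_flags_both_modes(self):
        rec = DailyRecord(dt.date(2012, 7, 25), 159.6, rain_mmh=10.2, light_wm2=350.0)
        assert flag_unreliable(rec, "excess_green")
        assert flag_unreliable(rec, "red_band")

    def test_darkness_flags_only_red_band(self):
        rec = DailyRecord(dt.date(2012, 7, 11), 87.2, rain_mmh=0.0, light_wm2=300.0)
        assert not flag_unreliable(rec, "excess_green")
        assert flag_unreliable(rec, "red_band")

    def test_missing_sensor_values_rejected(self):
        no_rain = DailyRecord(dt.date(2012, 7, 1), 77.0, light_wm2=700.0)
        with pytest.raises(ValueError, match="rain"):
            flag_unreliable(no_rain, "excess_green")
        no_light = DailyRecord(dt.date(2012, 7, 1), 77.0, rain_mmh=0.0)
        with pytest.raises(ValueError, match="light"):
            flag_unreliable(no_light, "red_band")
        with pytest.raises(ValueError):
            flag_unreliable(no_rain, "blue_band")


class TestInterpolateFlagged:
    def test_linear_midpoint_between_equidistant_neighbours(self):
        out = interpolate_flagged(_series([100, 130, 120], [False, True, False]), "linear")
        assert out.records[1].corrected_cm == pytest.approx(110.0)
        assert out.records[1].correction_source == "linear"

    def test_linear_weights_by_date_distance(self):
        s = HeightSeries(
            records=(
                DailyRecord(dt.date(2012, 7, 1), 100.0),
                DailyRecord(dt.date(2012, 7, 2), 0.0, flagged=True),
                DailyRecord(dt.date(2012, 7, 5), 140.0),
            )
        )
        out = interpolate_flagged(s, "linear")
        assert out.records[1].corrected_cm == pytest.approx(110.0)  # 1/4 of the way

    def test_previous_value_carried_forward(self):
        out = interpolate_flagged(_series([100, 130, 120], [False, True, False]), "previous")
        assert out.records[1].corrected_cm == pytest.approx(100.0)

    def test_single_neighbour_rule_at_series_start(self):
        out = interpolate_flagged(_series([50, 100], [True, False]), "linear")
        assert out.records[0].corrected_cm == pytest.approx(100.0)
        out_prev = interpolate_flagged(_series([50, 100], [True, False]), "previous")
        assert out_prev.records[0].corrected_cm == pytest.approx(100.0)

    def test_unflagged_records_untouched_and_idempotent(self):
        s = _series([100, 130, 120], [False, True, False])
        once = interpolate_flagged(s, "linear")
        assert once.records[0] == s.records[0]
        assert once.records[2] == s.records[2]
        twice = interpolate_flagged(once, "linear")
        assert twice == once
        assert all(r.corrected_cm is not None for r in once if r.flagged)

    def test_all_flagged_is_a_correction_error(self):
        with pytest.raises(CorrectionError):
            interpolate_flagged(_series([1, 2], [True, True]), "linear")

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            interpolate_flagged(_series([1.0], [False]), "spline")


class TestSummarizeErrors:
    def test_constant_list(self):
        assert summarize_errors([5, 5, 5]) == (5.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_errors([])

    @given(vals=st.lists(st.floats(0, 100), min_size=2, max_size=30))
    @settings(max_examples=40, derandomize=True)
    def test_matches_two_pass_oracle(self, vals):
        mean, sd = summarize_errors(vals)
        m = sum(vals) / len(vals)
        var = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)
        assert mean == pytest.approx(m, abs=1e-9)
        assert sd == pytest.approx(math.sqrt(var), abs=1e-9)


class TestCompareFeatures:
    def test_identical_samples_give_zero_t(self):
        t, p = compare_features_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_welch_formula(self):
        a, b = [0.0, 0.0, 10.0, 10.0], [0.0, 0.0, 0.0, 1.0]
        t, p = compare_features_t(a, b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        se = math.sqrt(va / len(a) + vb / len(b))
        assert t == pytest.approx((ma - mb) / se, abs=1e-12)

    def test_antisymmetric_under_swap(self):
        a, b = [1.0, 5.0, 9.0], [2.0, 2.5, 3.0, 8.0]
        t_ab, p_ab = compare_features_t(a, b)
        t_ba, p_ba = compare_features_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_short_lists_rejected(self):
        with pytest.raises(ValueError):
            compare_features_t([1.0], [1.0, 2.0])


class TestPackagedTables:
    @pytest.mark.parametrize("feature", ["red_band", "excess_green"])
    def test_tables_have_48_days_and_consistent_errors(self, feature):
        df = load_reference_table(feature)
        assert len(df) == 48
        assert df["date"].iloc[0] == "2012-07-01"
        assert df["date"].iloc[-1] == "2012-08-17"
        recomputed = [
            relative_error(e, r)
            for e, r in zip(df["estimated_cm"], df["referenced_cm"])
        ]
        # printed estimates are rounded to 0.1 cm, so printed errors can
        # deviate from Eq recomputation by up to ~0.08 points
        assert np.abs(np.asarray(recomputed) - df["relative_error_pct"]).max() < 0.1

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            load_reference_errors("green_band")


class TestHeightSeriesIO:
    def test_csv_round_trip(self, tmp_path):
        s = HeightSeries(
            records=(
                DailyRecord(dt.date(2012, 7, 1), 77.0, reference_cm=77.0,
                            condition="normal", light_wm2=700.0, rain_mmh=0.0),
                DailyRecord(dt.date(2012, 7, 2), 80.0, condition="darkness",
                            light_wm2=250.0, rain_mmh=0.0, flagged=False),
            )
        )
        path = tmp_path / "series.csv"
        s.to_csv(path)
        back = HeightSeries.from_csv(path)
        assert back == s

    def test_dates_must_strictly_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            HeightSeries(
                records=(
                    DailyRecord(dt.date(2012, 7, 2), 1.0),
                    DailyRecord(dt.date(2012, 7, 1), 2.0),
                )
            )
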