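"""Activity feature extraction and DAI computation."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import daindex as dx
from daindex.features import (
    compute_dai_table,
    dai_series,
    daily_features,
    nearest_rank_percentile,
)

from conftest import night_trace, noise_free_config


class TestAssignStudyDay:
    def test_evening_belongs_to_its_own_day(self, calendar, schedule):
        ts = pd.Timestamp(calendar.date_of(3)) + pd.Timedelta(hours=23)
        assert dx.assign_study_day(ts, calendar, schedule) == 3

    def test_post_midnight_belongs_to_previous_night(self, calendar, schedule):
        ts = pd.Timestamp(calendar.date_of(4)) + pd.Timedelta(hours=2)
        assert dx.assign_study_day(ts, calendar, schedule) == 3

    def test_noon_is_light_cycle_same_day(self, calendar, schedule):
        from daindex.features import label_samples

        ts = pd.Timestamp(calendar.date_of(3)) + pd.Timedelta(hours=12)
        assert dx.assign_study_day(ts, calendar, schedule) == 3
        day, dark = label_samples(pd.DatetimeIndex([ts]), calendar, schedule)
        assert day[0] == 3 and not dark[0]

    def test_before_study_range_rejected(self, calendar, schedule):
        ts = pd.Timestamp(calendar.date_of(calendar.study_start_day - 2))
        with pytest.raises(dx.DaindexError):
            dx.assign_study_day(ts, calendar, schedule)

    def test_degenerate_schedule_rejected(self):
        with pytest.raises(Exception):
            dx.LightSchedule(lights_on="06:00", lights_off="06:00")


class TestDailySalientFeature:
    def test_constant_night_any_method(self, calendar, schedule):
        trace = night_trace([20.0] * 720, 5, calendar, schedule)
        for method in ("q99", "max", "mean"):
            row = dx.daily_salient_feature(trace, 5, calendar, schedule, method=method)
            assert row["value"] == pytest.approx(20.0)
            assert row["coverage"] == pytest.approx(1.0)

    def test_enumerated_vector_max_and_q99(self, calendar, schedule):
        speeds = np.arange(1, 721, dtype=float)
        trace = night_trace(speeds, 5, calendar, schedule)
        assert dx.daily_salient_feature(trace, 5, calendar, schedule, "max")["value"] == 720.0
        # brute-force nearest-rank oracle: ceil(0.99 * n)-th smallest
        expected = sorted(speeds)[math.ceil(0.99 * len(speeds)) - 1]
        got = dx.daily_salient_feature(trace, 5, calendar, schedule, "q99")["value"]
        assert got == expected == 713.0

    def test_low_coverage_marks_missing(self, calendar, schedule):
        trace = night_trace([20.0] * 72, 5, calendar, schedule)  # 10% of the night
        row = dx.daily_salient_feature(trace, 5, calendar, schedule)
        assert math.isnan(row["value"])
        assert row["coverage"] == pytest.approx(0.1)

    def test_unknown_method_rejected(self, calendar, schedule):
        trace = night_trace([20.0] * 720, 5, calendar, schedule)
        with pytest.raises(dx.ConfigurationError):
            dx.daily_salient_feature(trace, 5, calendar, schedule, method="median")

    @given(
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=1, max_size=100),
    )
    def test_q99_and_max_match_sort_oracle_on_small_vectors(self, speeds):
        v = np.asarray(speeds)
        srt = sorted(v)
        assert nearest_rank_percentile(v, 99) == srt[math.ceil(0.99 * len(v)) - 1]
        assert nearest_rank_percentile(v, 100) == srt[-1] == np.max(v)


class TestBaseline:
    def _features(self, values_by_day):
        return pd.DataFrame(
            {
                "animal_id": "r1",
                "study_day": list(values_by_day),
                "value": list(values_by_day.values()),
                "coverage": 1.0,
            }
        )

    def test_constant_window(self, calendar):
        feats = self._features({d: 22.0 for d in calendar.baseline_days})
        b = dx.baseline_feature(feats, calendar)
        assert b.baseline_value == pytest.approx(22.0)
        assert b.n_days_used == len(calendar.baseline_days)

    def test_mean_of_nonmissing_days(self, calendar):
        feats = self._features({-2: 20.0, -1: 22.0, 1: 24.0})
        assert dx.baseline_feature(feats, calendar).baseline_value == pytest.approx(22.0)

    def test_day_zero_always_excluded(self, calendar):
        window = {d: 22.0 for d in calendar.baseline_days}
        window[0] = 5.0
        assert dx.baseline_feature(self._features(window), calendar).baseline_value == pytest.approx(22.0)

    def test_too_few_days_raises(self, calendar):
        feats = self._features({-2: 20.0, -1: 22.0})
        with pytest.raises(dx.BaselineError):
            dx.baseline_feature(feats, calendar, min_baseline_days=3)


class TestComputeDai:
    def test_identity_at_baseline(self):
        assert dx.compute_dai(22.0, 22.0) == 0.0

    def test_halved_activity_gives_half_scale(self):
        assert dx.compute_dai(11.0, 22.0, scale_k=20.0) == pytest.approx(10.0)

    def test_endpoint_magnitude(self):
        # a 43% activity drop maps near the severe-disease range
        assert dx.compute_dai(0.57 * 22.0, 22.0) == pytest.approx(8.6)

    def test_missing_value_propagates(self):
        assert math.isnan(dx.compute_dai(float("nan"), 22.0))

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(dx.DaindexError):
            dx.compute_dai(10.0, 0.0)

    @given(
        st.floats(1.0, 100.0),
        st.floats(0.0, 200.0),
        st.floats(0.0, 200.0),
    )
    def test_monotone_decreasing_in_daily_value(self, baseline, v1, v2):
        lo, hi = sorted([v1, v2])
        assert dx.compute_dai(lo, baseline) >= dx.compute_dai(hi, baseline)

    def test_clamped_at_zero_above_baseline(self):
        assert dx.compute_dai(30.0, 22.0) == 0.0


class TestMissingPropagation:
    def test_low_coverage_day_never_reaches_baseline_or_dai(self, calendar, schedule, feature_cfg):
        # full nights on enough baseline days, a 10%-covered day elsewhere
        frames = []
        for d in (-2, -1, 1, 2):
            frames.append(night_trace([22.0] * 720, d, calendar, schedule).samples)
        frames.append(night_trace([5.0] * 72, 3, calendar, schedule).samples)
        trace = dx.ActivityTrace("r1", pd.concat(frames, ignore_index=True))
        feats = daily_features(trace, calendar, schedule)
        base = dx.baseline_feature(feats, calendar)
        assert base.baseline_value == pytest.approx(22.0)  # bad day not in window anyway
        table = dai_series(feats, base)
        assert math.isnan(table.set_index("study_day").loc[3, "dai"])

    def test_low_coverage_baseline_day_excluded_from_baseline(self, calendar, schedule):
        frames = []
        for d in (-2, -1, 1):
            frames.append(night_trace([22.0] * 720, d, calendar, schedule).samples)
        frames.append(night_trace([5.0] * 72, 2, calendar, schedule).samples)  # in window
        trace = dx.ActivityTrace("r1", pd.concat(frames, ignore_index=True))
        feats = daily_features(trace, calendar, schedule)
        base = dx.baseline_feature(feats, calendar)
        assert base.baseline_value == pytest.approx(22.0)
        assert base.n_days_used == 3


class TestNightMotionAndPercentDecrease:
    def test_constant_nights(self, calendar, schedule):
        frames = [night_trace([21.7] * 720, d, calendar, schedule).samples for d in (-3, -2, -1)]
        trace = dx.ActivityTrace("r1", pd.concat(frames, ignore_index=True))
        assert dx.mean_night_motion(trace, [-3, -2, -1], calendar, schedule) == pytest.approx(21.7)

    def test_two_nights_equal_counts_average(self, calendar, schedule):
        frames = [
            night_trace([20.0] * 720, 1, calendar, schedule).samples,
            night_trace([24.0] * 720, 2, calendar, schedule).samples,
        ]
        trace = dx.ActivityTrace("r1", pd.concat(frames, ignore_index=True))
        assert dx.mean_night_motion(trace, [1, 2], calendar, schedule) == pytest.approx(22.0)

    def test_simulated_night_motion_matches_generator_expectation(self, calendar, schedule):
        from daindex.simulate import LatentDiseaseState, expected_dark_mean, simulate_trace

        cfg = dx.SimulationConfig(seed=5)
        state = LatentDiseaseState("r1", ramp_start=9.0, endpoint_severity=0.9,
                                   baseline_speed=22.0)
        trace = simulate_trace(state, cfg, schedule, calendar,
                               rng=np.random.default_rng(5))
        for day in (13, 17):
            v = dx.mean_night_motion(trace, [day], calendar, schedule)
            mu = expected_dark_mean(state, cfg, day)
            se = cfg.within_noise_cv * mu / math.sqrt(720)
            assert abs(v - mu) < 3 * se

    def test_percent_decrease_values(self):
        assert dx.percent_decrease(21.7, 18.6) == 14
        assert dx.percent_decrease(5.0, 5.0) == 0
        assert dx.percent_decrease(22.3, 12.4) == 44

    def test_percent_decrease_domain(self):
        with pytest.raises(dx.DaindexError):
            dx.percent_decrease(0.0, 1.0)


class TestBaselineWindowDai:
    def test_noise_only_cohort_has_near_zero_baseline_dai(self, calendar, schedule, feature_cfg):
        cfg = dx.SimulationConfig(seed=8)
        ds = dx.simulate_cohort(cfg, [dx.GroupSpec(name="Ctl", n=4, induced=False)])
        _, dai, _, excluded = compute_dai_table(ds.traces, calendar, schedule, feature_cfg)
        assert not excluded
        window = dai[dai["study_day"].isin(calendar.baseline_days)]
        assert abs(window["dai"].mean()) < feature_cfg.scale_k * cfg.within_noise_cv
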