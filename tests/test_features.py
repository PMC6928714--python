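"""Moving-percentile features, tremor transform and the weekly BKS series."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkg_ldct import features
from pkg_ldct._percentiles import sliding_weighted_percentile, triangular_weights
from pkg_ldct.epoch_store import Recording, DoseEvent, label_activity

from _oracles import moving_percentile_oracle

QS = (10.0, 25.0, 50.0, 75.0, 90.0)


class TestMovingPercentiles:
    def test_median_of_1_to_15_is_8(self):
        out = features.moving_percentile(np.arange(1.0, 16.0), 15, 50.0)
        assert out[7] == 8.0

    def test_constant_series_returns_constant_for_any_q(self):
        series = np.full(40, 3.25)
        for q in QS:
            assert np.allclose(features.moving_percentile(series, 15, q), 3.25)
            assert np.allclose(features.weighted_moving_percentile(series, 15, q), 3.25)

    def test_hand_cumulative_weight_example(self):
        # window [0, 10, excluded] with weights [3, 1, -]: cumulative weight
        # at the first value is 0.75 >= 0.5, so the weighted median is 0
        out = sliding_weighted_percentile(
            np.array([0.0, 10.0, np.nan]), 3, 50.0, np.array([3.0, 1.0, 1.0])
        )
        assert out[1] == 0.0

    @pytest.mark.parametrize("q", QS)
    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_bruteforce_oracle_on_random_series(self, q, weighted):
        rng = np.random.default_rng(int(q) + weighted)
        for rep in range(8):  # 8 x 150 positions per (q, kernel) case
            series = rng.normal(size=150)
            series[rng.random(150) < 0.2] = np.nan  # excluded epochs
            weights = triangular_weights(15) if weighted else None
            got = sliding_weighted_percentile(series, 15, q, weights)
            expected = moving_percentile_oracle(series, 15, q, weights)
            np.testing.assert_array_equal(got, expected)

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_uniform_kernel_degenerates_to_unweighted(self, values):
        series = np.asarray(values)
        got = sliding_weighted_percentile(series, 7, 25.0, np.ones(7))
        expected = features.moving_percentile(series, 7, 25.0)
        np.testing.assert_array_equal(got, expected)

    def test_nondecreasing_in_q_and_translation_equivariant(self):
        rng = np.random.default_rng(0)
        series = rng.normal(10, 5, 200)
        prev = None
        for q in QS:
            cur = features.weighted_moving_percentile(series, 15, q)
            if prev is not None:
                assert np.all(cur >= prev - 1e-12)
            prev = cur
        shifted = features.weighted_moving_percentile(series + 4.5, 15, 50.0)
        base = features.weighted_moving_percentile(series, 15, 50.0)
        np.testing.assert_allclose(shifted, base + 4.5)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            features.moving_percentile(np.zeros(10), 15, 0.0)
        with pytest.raises(ValueError):
            features.moving_percentile(np.zeros(10), 15, 100.0)
        with pytest.raises(ValueError):
            features.moving_percentile(np.zeros(10), 14, 50.0)

    def test_all_excluded_window_yields_missing(self):
        series = np.full(9, np.nan)
        assert np.all(np.isnan(features.moving_percentile(series, 5, 50.0)))


class TestLogTremor:
    @pytest.mark.parametrize("ta,expected", [(0.0, 0.0), (9.0, 1.0), (99.0, 2.0)])
    def test_decades(self, ta, expected):
        assert features.log_tremor(ta) == pytest.approx(expected)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            features.log_tremor(-1.0)


def _flat_recording(bks_values, doses=None, subject="s1", group="PwP"):
    n = len(bks_values)
    epochs = pd.DataFrame(
        {
            "timestamp_min": np.arange(n) * 2,
            "bks": np.asarray(bks_values, dtype=float),
            "tremor_amplitude": np.zeros(n),
            "off_wrist": np.zeros(n, dtype=bool),
        }
    )
    return Recording(subject_id=subject, group=group, epochs=epochs, dose_events=doses or [])


class TestWeeklySeries:
    def test_single_day_no_smoothing_equals_aligned_bks(self):
        rng = np.random.default_rng(1)
        bks = rng.uniform(5, 30, 300)
        dose = DoseEvent(reminder_min=100.0, acknowledgement_min=100.0, first_of_day=True)
        rec = _flat_recording(bks, [dose])
        act = np.full(300, "active", dtype=object)
        series = features.smoothed_weekly_series(
            rec, act, offset_range=(-20, 60), smooth_window=1
        )
        anchor = 50  # epoch index of minute 100
        for offset, value in zip(series.offsets, series.values):
            np.testing.assert_allclose(value, bks[anchor + offset // 2])

    def test_identical_days_collapse_to_one_day_profile(self):
        day = np.concatenate([np.full(360, 20.0), np.full(360, 12.0)])
        bks = np.tile(day, 6)
        doses = [
            DoseEvent(reminder_min=1440.0 * d + 400, acknowledgement_min=1440.0 * d + 400, first_of_day=True)
            for d in range(6)
        ]
        rec = _flat_recording(bks, doses)
        act = np.full(len(bks), "active", dtype=object)
        six = features.smoothed_weekly_series(rec, act, offset_range=(-60, 120))
        one = features.smoothed_weekly_series(
            rec, act, align_times=[400.0], offset_range=(-60, 120)
        )
        np.testing.assert_allclose(six.values, one.values)
        assert np.all(six.n_days_contributing >= 5)

    def test_median_robust_to_single_day_outlier(self):
        day = np.full(720, 15.0)
        bks = np.tile(day, 6).astype(float)
        bks[3 * 720 : 4 * 720] = 90.0  # one aberrant day
        doses = [
            DoseEvent(reminder_min=1440.0 * d + 400, acknowledgement_min=1440.0 * d + 400, first_of_day=True)
            for d in range(6)
        ]
        rec = _flat_recording(bks, doses)
        act = np.full(len(bks), "active", dtype=object)
        series = features.smoothed_weekly_series(rec, act, offset_range=(0, 100))
        full = series.n_days_contributing == 6
        np.testing.assert_allclose(series.values[full], 15.0)

    def test_no_acknowledged_dose_raises(self):
        rec = _flat_recording(np.full(100, 10.0))
        act = np.full(100, "active", dtype=object)
        with pytest.raises(features.EmptySeriesError):
            features.smoothed_weekly_series(rec, act)


class TestFeaturize:
    def test_zero_tremor_window_gives_zero_log_feature(self, quick_cohort):
        recordings, _ = quick_cohort
        rec = next(r for r in recordings if r.group == "control")
        act = label_activity(rec)
        table = features.featurize(rec, act)
        usable = table[table["usable"]]
        assert np.allclose(usable["TA_WM50P_Log"].dropna(), 0.0)

    def test_percentile_ordering_invariant(self, quick_cohort):
        recordings, _ = quick_cohort
        table = features.featurize(recordings[0], label_activity(recordings[0]))
        cols = [f"BKS_M{q}P" for q in (10, 25, 50, 75, 90)]
        vals = table[cols].dropna().to_numpy()
        assert np.all(np.diff(vals, axis=1) >= -1e-12)
        wcols = [f"BKS_WM{q}P" for q in (10, 25, 50, 75, 90)]
        wvals = table[wcols].dropna().to_numpy()
        assert np.all(np.diff(wvals, axis=1) >= -1e-12)

    def test_selected_feature_set_has_three_members(self):
        assert len(features.SELECTED_FEATURES) == 3
        assert set(features.SELECTED_FEATURES) == {"BKS_M10P", "BKS_M25P", "TA_WM50P_Log"}

    def test_off_wrist_bks_never_influences_features(self, quick_cohort):
        recordings, _ = quick_cohort
        rec = recordings[0]
        off = rec.epochs["off_wrist"].to_numpy()
        assert off.any()
        tampered = Recording(
            subject_id=rec.subject_id,
            group=rec.group,
            epochs=rec.epochs.assign(bks=np.where(off, 1e6, rec.epochs["bks"])),
            dose_events=rec.dose_events,
            clinical=rec.clinical,
        )
        act1, act2 = label_activity(rec), label_activity(tampered)
        np.testing.assert_array_equal(act1, act2)
        t1 = features.featurize(rec, act1)
        t2 = features.featurize(tampered, act2)
        for col in features.FEATURE_COLUMNS:
            np.testing.assert_array_equal(t1[col].to_numpy(), t2[col].to_numpy())
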