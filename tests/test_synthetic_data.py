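"""Generator contracts: determinism, ground-truth structure and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pkg_ldct import synthetic_data as sd
from pkg_ldct.epoch_store import label_activity
from pkg_ldct.features import smoothed_weekly_series


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SimulationConfig(n_pwp=-1)

    def test_out_of_range_rates_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SimulationConfig(inactivity_rate=1.5)
        with pytest.raises(sd.ConfigurationError):
            sd.SimulationConfig(offwrist_rate=-0.1)

    def test_zero_days_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SimulationConfig(n_days=0)


class TestDeterminism:
    def test_identical_config_and_seed_reproduce_the_cohort(self):
        config = sd.SimulationConfig(n_pwp=3, n_controls=2, n_days=2, seed=13)
        recs1, truths1 = sd.simulate_cohort(config)
        recs2, truths2 = sd.simulate_cohort(config)
        assert truths1 == truths2
        for a, b in zip(recs1, recs2):
            pd.testing.assert_frame_equal(a.epochs, b.epochs)
            assert a.dose_events == b.dose_events
            assert a.clinical == b.clinical

    def test_different_seeds_differ(self):
        r1, _ = sd.simulate_cohort(sd.SimulationConfig(n_pwp=1, n_controls=0, n_days=1, seed=1))
        r2, _ = sd.simulate_cohort(sd.SimulationConfig(n_pwp=1, n_controls=0, n_days=1, seed=2))
        assert not np.allclose(r1[0].epochs["bks"], r2[0].epochs["bks"])


class TestCohortStructure:
    def test_controls_only_cohort(self):
        recs, truths = sd.simulate_cohort(
            sd.SimulationConfig(n_pwp=0, n_controls=10, n_days=2, seed=3)
        )
        assert len(recs) == 10
        assert all(t.updrs_off == 0.0 and t.updrs_on == 0.0 for t in truths)
        assert all(not r.dose_events for r in recs)

    def test_pwp_have_one_first_dose_per_day(self, quick_cohort):
        recordings, truths = quick_cohort
        for rec, truth in zip(recordings, truths):
            if truth.group != "PwP":
                continue
            firsts = rec.first_of_day_events()
            assert len(firsts) == 3  # one per simulated day
            days = {int(d.reminder_min // 1440) for d in firsts}
            assert len(days) == 3

    def test_truth_invariants(self, quick_cohort):
        _, truths = quick_cohort
        for t in truths:
            assert t.updrs_on <= t.updrs_off
            if t.group == "PwP":
                assert 46.0 <= t.response_latency_mean <= 90.0

    def test_sleep_epochs_detected_inactive(self, quick_cohort):
        recordings, _ = quick_cohort
        rec = recordings[0]
        labels = label_activity(rec)
        tod = rec.epochs["timestamp_min"].to_numpy() % 1440
        night = (tod >= 120) & (tod < 300)  # 02:00-05:00, deep in the sleep bout
        on_wrist_night = night & (labels != "off_wrist")
        assert (labels[on_wrist_night] == "inactive").mean() > 0.95

    def test_already_on_morning_below_afternoon(self):
        config = sd.SimulationConfig(
            n_pwp=30, n_controls=0, n_days=2, seed=21, frac_already_on=1.0
        )
        recs, truths = sd.simulate_cohort(config)
        checked = 0
        for rec, truth in zip(recs, truths):
            if not truth.already_on:
                continue
            tod = rec.epochs["timestamp_min"].to_numpy() % 1440
            labels = label_activity(rec)
            active = labels == "active"
            bks = rec.epochs["bks"].to_numpy()
            morning = active & (tod >= 480) & (tod < 600)
            afternoon = active & (tod >= 840) & (tod < 1020)
            assert bks[morning].mean() < bks[afternoon].mean()
            checked += 1
        assert checked >= 15


class TestLinkMonotonicity:
    def test_mean_dt_bks_increases_with_untreated_severity(self):
        # Monte-Carlo over strata: severe PwP vs controls (UPDRS III 0)
        config = sd.SimulationConfig(n_pwp=120, n_controls=30, n_days=3, seed=8)
        recs, truths = sd.simulate_cohort(config)
        strata = {"low": [], "mid": [], "high": []}
        for rec, truth in zip(recs, truths):
            labels = label_activity(rec)
            active = labels == "active"
            if truth.group == "control":
                anchors = [d * 1440 + 420 for d in range(config.n_days)]
            else:
                anchors = [e.acknowledgement_min for e in rec.first_of_day_events()]
            ts = rec.epochs["timestamp_min"].to_numpy()
            sel = np.zeros(len(ts), dtype=bool)
            for a in anchors:
                sel |= (ts >= a - 4) & (ts <= a + 4)
            usable = sel & active
            if not usable.any():
                continue
            mean_bks = rec.epochs["bks"].to_numpy()[usable].mean()
            if truth.updrs_off == 0:
                strata["low"].append(mean_bks)
            elif truth.updrs_off >= 55:
                strata["high"].append(mean_bks)
            else:
                strata["mid"].append(mean_bks)
        assert min(len(v) for v in strata.values()) >= 20
        assert np.mean(strata["low"]) < np.mean(strata["mid"]) < np.mean(strata["high"])


class TestCalibration:
    def test_latency_sampler_recovers_truncated_normal_moments(self):
        rng = np.random.default_rng(0)
        config = sd.SimulationConfig()
        lo, hi = config.latency_support
        draws = sd.truncated_normal(rng, config.latency_mean, config.latency_sd, lo, hi, size=2000)
        a = (lo - config.latency_mean) / config.latency_sd
        b = (hi - config.latency_mean) / config.latency_sd
        expected_mean, expected_var = stats.truncnorm.stats(
            a, b, loc=config.latency_mean, scale=config.latency_sd, moments="mv"
        )
        se_mean = np.sqrt(expected_var / draws.size)
        assert abs(draws.mean() - expected_mean) < 2 * se_mean
        assert abs(draws.std(ddof=1) - np.sqrt(expected_var)) < 0.15 * np.sqrt(expected_var)

    def test_detected_weekly_trough_tracks_subject_latency(self):
        # strong responders with tight day-to-day latency: the weekly-series
        # trough should land near the subject's latency mean
        config = sd.SimulationConfig(
            n_pwp=12, n_controls=0, n_days=6, seed=17,
            frac_already_on=0.0, frac_high_variability=0.0, latency_day_sd=3.0,
        )
        recs, truths = sd.simulate_cohort(config)
        errors = []
        for rec, truth in zip(recs, truths):
            if truth.updrs_off - truth.updrs_on < 15:
                continue
            labels = label_activity(rec)
            weekly = smoothed_weekly_series(rec, labels)
            sub = weekly.window(46, 90)
            detected = sub.offsets[np.nanargmin(sub.values)]
            errors.append(abs(detected - truth.response_latency_mean))
        assert len(errors) >= 6
        assert np.median(errors) <= 10.0

    def test_inactivity_bout_occupancy_matches_rate(self):
        rng = np.random.default_rng(5)
        n, rate, mean_len = 200_000, 0.15, 10.0
        mask = sd.bout_mask(rng, n, np.ones(n, dtype=bool), rate, mean_len)
        # bouts are autocorrelated: effective sample size ~ n / (2 * mean bout)
        se = np.sqrt(rate * (1 - rate) / (n / (2 * mean_len)))
        assert abs(mask.mean() - rate) < 2 * se


class TestControlsDay:
    def test_no_doses_and_ten_oclock_epoch_exists(self):
        rec = sd.simulate_controls_day(sd.SimulationConfig(seed=4, n_days=6))
        assert rec.dose_events == []
        for day in range(6):
            assert rec.epoch_index_of(day * 1440 + 600) is not None

    def test_no_dose_locked_trough_after_nominal_dose_time(self):
        rec = sd.simulate_controls_day(sd.SimulationConfig(seed=4, n_days=6))
        labels = label_activity(rec)
        active = labels == "active"
        ts = rec.epochs["timestamp_min"].to_numpy()
        bks = rec.epochs["bks"].to_numpy()
        at_dt, post = [], []
        for day in range(6):
            dt = day * 1440 + 600
            at_dt.extend(bks[active & (ts >= dt - 4) & (ts <= dt + 4)])
            post.extend(bks[active & (ts >= dt + 46) & (ts <= dt + 90)])
        diff = np.mean(post) - np.mean(at_dt)
        se = np.sqrt(np.var(post) / len(post) + np.var(at_dt) / len(at_dt))
        assert abs(diff) < 2 * se + 1e-9

    def test_daytime_fully_usable_without_exclusion_processes(self):
        config = sd.SimulationConfig(seed=9, n_days=2, inactivity_rate=0.0, offwrist_rate=0.0)
        rec = sd.simulate_controls_day(config)
        labels = label_activity(rec)
        tod = rec.epochs["timestamp_min"].to_numpy() % 1440
        daytime = (tod >= 600) & (tod < 1320)  # clear of the sleep bouts
        assert set(labels[daytime]) == {"active"}
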