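"""Generator: determinism, noise calibration, motion model, response injection."""

import numpy as np
import pytest

from stresswear import (
    CircadianProfile,
    ConfigurationError,
    Event,
    ResponseParams,
    SimConfig,
    inject_event_response,
    rmssd,
    simulate_cohort,
    simulate_motion_stream,
    simulate_rr_stream,
)

HOUR = 3600.0


def _assert_user_equal(a, b):
    np.testing.assert_array_equal(a.beats.beat_time_s, b.beats.beat_time_s)
    np.testing.assert_array_equal(a.beats.rr_ms, b.beats.rr_ms)
    np.testing.assert_array_equal(a.motion.magnitude_g, b.motion.magnitude_g)
    assert a.events == b.events
    np.testing.assert_array_equal(a.present_days, b.present_days)


class TestCohort:
    def test_seeded_determinism(self):
        cfg = SimConfig(n_users=2, n_days=3, rng_seed=7, missing_day_prob=0.0,
                        events_per_user={"run": 1})
        d1 = simulate_cohort(cfg)
        d2 = simulate_cohort(cfg)
        for u1, u2 in zip(d1.users, d2.users):
            _assert_user_equal(u1, u2)
        assert d1.ground_truth.events == d2.ground_truth.events

    def test_no_missingness_gives_all_days(self):
        cfg = SimConfig(n_users=3, n_days=5, rng_seed=1, missing_day_prob=0.0,
                        events_per_user={})
        ds = simulate_cohort(cfg)
        for u in ds.users:
            assert u.present_days.size == 5

    def test_ground_truth_bookkeeping(self):
        cfg = SimConfig(n_users=10, n_days=6, rng_seed=3, missing_day_prob=0.0,
                        events_per_user={"run": 4})
        ds = simulate_cohort(cfg)
        assert len(ds.ground_truth.events) == 40
        assert all(e["type"] == "run" for e in ds.ground_truth.events)
        # exactly one record per simulated event
        sim_ids = {e.event_id for u in ds.users for e in u.events}
        gt_ids = {e["event_id"] for e in ds.ground_truth.events}
        assert sim_ids == gt_ids

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="missing_day_prob"):
            simulate_cohort(SimConfig(n_users=1, missing_day_prob=1.5))
        with pytest.raises(ConfigurationError, match="hr_mesor_bpm"):
            simulate_cohort(SimConfig(n_users=1, hr_mesor_bpm=150))

    def test_streams_physical(self, small_cohort):
        for u in small_cohort.users:
            assert np.all(u.beats.rr_ms > 0)
            assert np.all(np.diff(u.beats.beat_time_s) > 0)
            assert np.all(u.motion.magnitude_g >= 0)


class TestRRStream:
    def test_constant_hr_noiseless_rr(self):
        prof = CircadianProfile(60.0, 0.0, 50.0, 0.0, 3.0, 6.0)
        beats = simulate_rr_stream(prof, 0, HOUR, np.random.default_rng(0),
                                   noiseless=True)
        assert np.allclose(beats.rr_ms, 1000.0)
        assert np.allclose(np.diff(beats.beat_time_s), 1.0)

    def test_zero_hrv_target_gives_exact_rr(self):
        # degenerate noiseless limit: sigma = 0 even on the noisy path
        prof = CircadianProfile(72.0, 0.05, 0.0, 0.0, 3.0, 6.0)
        beats = simulate_rr_stream(prof, 0, 6 * HOUR, np.random.default_rng(1))
        t_prev = np.concatenate(([0.0], beats.beat_time_s[:-1]))
        assert np.allclose(beats.rr_ms, 60000.0 / prof.hr(t_prev))

    def test_rmssd_noise_calibration(self, flat_profile):
        """White noise with sigma = HRV/sqrt(2) yields stream RMSSD at the
        target, within 2% over >= 1e5 beats."""
        rng = np.random.default_rng(2)
        span = 1e5 * 60.0 / flat_profile.hr_mesor_bpm
        beats = simulate_rr_stream(flat_profile, 0, span, rng)
        assert beats.rr_ms.size >= 1e5
        assert rmssd(beats.rr_ms) == pytest.approx(50.0, rel=0.02)

    def test_noiseless_windowed_hr_matches_circadian_curve(self):
        from stresswear import compute_metric_windows, MotionSeries

        prof = CircadianProfile(65.0, 0.07, 0.0, 0.0, 3.0, 6.0)
        beats = simulate_rr_stream(prof, 0, 86400.0, np.random.default_rng(0),
                                   noiseless=True)
        t = np.arange(0, 86400.0, 1.0)
        w = compute_metric_windows(beats, MotionSeries(t, np.zeros(t.size), 1.0))
        hr_true = prof.hr(w["center_time_s"].to_numpy())
        assert np.nanmax(np.abs(w["hr_motionless_bpm"] - hr_true)) < 0.1

    def test_nonpositive_hr_rejected(self):
        prof = CircadianProfile(60.0, 0.0, 10.0, 0.0, 3.0, 6.0, responses=(
            (Event("e", "u", "high_stress_work", 100.0, 200.0),
             ResponseParams(-100.0, 0.0, 60.0, 60.0, -100.0, 0.0)),
        ))
        with pytest.raises(ConfigurationError):
            simulate_rr_stream(prof, 0, HOUR, np.random.default_rng(0))


class TestMotionStream:
    def test_quiet_stream_below_threshold(self):
        m = simulate_motion_stream(
            0, HOUR, (), np.random.default_rng(0),
            rest_sigma_g=0.005, fidget_rate_per_h=0.0,
        )
        assert np.all(np.abs(m.magnitude_g) < 0.05)

    def test_run_interval_fully_high_motion(self):
        run = Event("r", "u", "run", 10 * HOUR, 10 * HOUR + 40 * 60, load="light")
        m = simulate_motion_stream(
            0, 12 * HOUR, (run,), np.random.default_rng(0),
            rest_sigma_g=0.005, fidget_rate_per_h=0.0,
        )
        sel = (m.sample_time_s >= run.start_s) & (m.sample_time_s < run.end_s)
        assert np.all(m.magnitude_g[sel] > 0.05)

    def test_fidget_count_matches_poisson_rate(self):
        """Bout count over many seeds matches the configured rate."""
        rate, hours = 3.0, 12.0
        counts = []
        for seed in range(40):
            m = simulate_motion_stream(
                0, hours * HOUR, (), np.random.default_rng(seed),
                rest_sigma_g=1e-4, fidget_rate_per_h=rate,
                fidget_duration_s=(20.0, 40.0),
            )
            above = m.magnitude_g > 0.05
            bouts = int(np.sum(np.diff(above.astype(int)) == 1) + above[0])
            counts.append(bouts)
        expected = rate * hours
        se = np.sqrt(expected / len(counts))
        # bouts can merge when two fidgets overlap, so allow a small deficit
        assert abs(np.mean(counts) - expected) < 4 * se + 1.0


class TestInjectEventResponse:
    def _base_beats(self, flat_profile, span=12 * HOUR, seed=3):
        return simulate_rr_stream(flat_profile, 0, span, np.random.default_rng(seed))

    def test_null_response_is_identity(self, flat_profile):
        beats = self._base_beats(flat_profile)
        ev = Event("e", "u", "run", 2 * HOUR, 3 * HOUR, load="light")
        out = inject_event_response(beats, ev, ResponseParams(0, 0, 60, 60))
        np.testing.assert_array_equal(out.rr_ms, beats.rr_ms)
        np.testing.assert_array_equal(out.beat_time_s, beats.beat_time_s)

    def test_bin_averaged_offset_matches_closed_form(self):
        """Mean HR offset over (0, 30] min post-event equals the exponential's
        bin average delta * (tau/D) * (1 - exp(-D/tau))."""
        prof = CircadianProfile(60.0, 0.0, 0.0, 0.0, 3.0, 6.0)
        beats = simulate_rr_stream(prof, 0, 8 * HOUR, np.random.default_rng(0),
                                   noiseless=True)
        ev = Event("e", "u", "high_stress_work", 2 * HOUR, 3 * HOUR)
        delta, tau = 6.0, 60.0
        out = inject_event_response(
            beats, ev, ResponseParams(delta, 0.0, tau, 60.0)
        )
        t_prev = np.concatenate(([0.0], out.beat_time_s[:-1]))
        hr = 60000.0 / out.rr_ms
        sel = (t_prev > ev.end_s) & (t_prev <= ev.end_s + 30 * 60.0)
        measured = np.mean(hr[sel]) - 60.0
        expected = delta * (tau / 30.0) * (1 - np.exp(-30.0 / tau))
        assert measured == pytest.approx(expected, rel=0.01)

    def test_offset_decays_to_under_one_percent_at_five_tau(self):
        prof = CircadianProfile(60.0, 0.0, 0.0, 0.0, 3.0, 6.0)
        beats = simulate_rr_stream(prof, 0, 12 * HOUR, np.random.default_rng(0),
                                   noiseless=True)
        ev = Event("e", "u", "high_stress_work", HOUR, 2 * HOUR)
        delta, tau_min = 8.0, 60.0
        out = inject_event_response(beats, ev, ResponseParams(delta, 0, tau_min, 60))
        t_prev = np.concatenate(([0.0], out.beat_time_s[:-1]))
        hr = 60000.0 / out.rr_ms
        late = t_prev > ev.end_s + 5 * tau_min * 60.0
        assert np.all(np.abs(hr[late] - 60.0) < 0.01 * delta)

    def test_hrv_suppression_floors_at_one_ms(self, flat_profile):
        beats = self._base_beats(flat_profile)
        ev = Event("e", "u", "high_stress_work", HOUR, 2 * HOUR)
        out = inject_event_response(
            beats, ev, ResponseParams(0.0, 500.0, 60.0, 60.0, 0.0, -500.0)
        )
        assert np.all(out.profile.hrv(np.linspace(HOUR, 3 * HOUR, 500)) >= 1.0)

    def test_out_of_range_response_rejected(self, flat_profile):
        beats = self._base_beats(flat_profile)
        ev = Event("e", "u", "high_stress_work", HOUR, 2 * HOUR)
        with pytest.raises(ConfigurationError):
            inject_event_response(
                beats, ev, ResponseParams(300.0, 0.0, 60.0, 60.0, 300.0, 0.0)
            )
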