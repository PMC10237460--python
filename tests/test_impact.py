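"""Event binning, double normalization, load surrogate, trapezoidal AUC."""

import numpy as np
import pandas as pd
import pytest

from stresswear import (
    Event,
    InsufficientDataError,
    bin_event_deviation,
    classify_run_load,
    event_auc,
)
from stresswear.impact import POST_LABELS
from test_baseline import _mk_baseline
from conftest import synthetic_windows

HOUR = 3600.0
MIN = 60.0


class TestClassifyRunLoad:
    def test_below_half_hrr_is_light(self):
        hr = np.full(30, 100.0)  # 40% HRR with rest 60, max 160
        assert classify_run_load(hr, 160.0, 60.0) == "light"

    def test_sustained_65pct_is_moderate(self):
        # 45 min at 65% HRR -> zone weight 2 -> score 90
        hr = np.full(45, 60.0 + 0.65 * 100.0)
        assert classify_run_load(hr, 160.0, 60.0) == "moderate"

    def test_hour_at_85pct_is_vigorous(self):
        # 60 min at 85% HRR -> zone weight 4 -> score 240
        hr = np.full(60, 60.0 + 0.85 * 100.0)
        assert classify_run_load(hr, 160.0, 60.0) == "vigorous"

    def test_no_samples_unclassifiable(self):
        with pytest.raises(InsufficientDataError):
            classify_run_load([], 160.0, 60.0)

    def test_invalid_reserve(self):
        with pytest.raises(ValueError):
            classify_run_load([100.0], 60.0, 160.0)


def _flat_windows(hr=60.0, hrv=50.0, t0=0.0, t1=12 * HOUR):
    t = np.arange(t0, t1, 30.0)
    return synthetic_windows(np.full(t.size, hr), np.full(t.size, hrv), t)


class TestBinEventDeviation:
    def test_stream_at_baseline_gives_zero_bins(self):
        w = _flat_windows()
        ev = Event("e", "u", "high_stress_work", 3 * HOUR, 4 * HOUR)
        out = bin_event_deviation(w, ev, _mk_baseline(60.0, 60.0, 50.0, 50.0))
        assert np.allclose(out["delta_hr_bpm"], 0.0)
        assert np.allclose(out["delta_hrv_ms"], 0.0)
        assert set(out["bin_label"]) == {"Pre", "During", *POST_LABELS}

    def test_pre_bin_identically_zero(self):
        w = _flat_windows(hr=64.0)
        ev = Event("e", "u", "high_stress_work", 3 * HOUR, 4 * HOUR)
        out = bin_event_deviation(w, ev, _mk_baseline(60.0, 60.0, 50.0, 50.0))
        pre = out.loc[out["bin_label"] == "Pre"].iloc[0]
        assert pre["delta_hr_bpm"] == 0.0 and pre["delta_hrv_ms"] == 0.0

    def test_injected_step_recovered(self):
        """+6 bpm for 60 min post-event shows in bins 0-30 / 30-60 only."""
        w = _flat_windows()
        ev = Event("e", "u", "run", 3 * HOUR, 4 * HOUR, load="light")
        t = w["center_time_s"].to_numpy()
        step = (t >= ev.end_s) & (t < ev.end_s + 60 * MIN)
        w.loc[step, "hr_motionless_bpm"] += 6.0
        out = bin_event_deviation(w, ev, _mk_baseline(60.0, 60.0, 50.0, 50.0))
        by = out.set_index("bin_label")["delta_hr_bpm"]
        assert by["0-30"] == pytest.approx(6.0, abs=0.1)
        assert by["30-60"] == pytest.approx(6.0, abs=0.1)
        assert np.allclose(by[POST_LABELS[2:]], 0.0, atol=0.1)
        assert "During" not in by.index  # runs have no During bin

    def test_straddling_baseline_hours_matches_naive_oracle(self):
        """Bin normalization uses the hourly median of the bin-center hour."""
        base = _mk_baseline(60.0, 60.0, 50.0, 50.0)
        base.median_hr_bpm[4] = 58.0
        base.median_hr_bpm[5] = 63.0
        w = _flat_windows(hr=65.0)
        # event ends at 4:15; bins 0-30 centred 4:30 (hour 4), 30-60 at 5:00
        ev = Event("e", "u", "run", 3.5 * HOUR, 4.25 * HOUR, load="light")
        out = bin_event_deviation(w, ev, base)
        by = out.set_index("bin_label")["delta_hr_bpm"]
        pre_norm = 65.0 - base.median_hr_bpm[2]  # Pre centred 3:15 -> hour 3
        assert by["0-30"] == pytest.approx((65.0 - 58.0) - pre_norm)
        assert by["30-60"] == pytest.approx((65.0 - 63.0) - pre_norm)

    def test_event_without_valid_pre_excluded(self):
        w = _flat_windows()
        t = w["center_time_s"].to_numpy()
        ev = Event("e", "u", "run", 3 * HOUR, 4 * HOUR, load="light")
        pre = (t >= ev.start_s - 30 * MIN) & (t < ev.start_s)
        w.loc[pre, "valid"] = False
        assert bin_event_deviation(w, ev, _mk_baseline(60, 60, 50, 50)) is None

    def test_contaminated_bins_dropped(self):
        w = _flat_windows()
        ev = Event("e", "u", "run", 3 * HOUR, 4 * HOUR, load="light")
        other = Event("o", "u", "run", 5 * HOUR, 5.5 * HOUR, load="light")
        out = bin_event_deviation(
            w, ev, _mk_baseline(60, 60, 50, 50), other_events=[ev, other]
        )
        # the other run occupies 60-90 min after ev's end
        assert "60-90" not in set(out["bin_label"])
        assert "90-120" not in set(out["bin_label"])
        assert "0-30" in set(out["bin_label"])

    def test_constant_offset_annihilated(self):
        """Adding c bpm to the stream and to the baseline leaves deltas
        unchanged (double normalization kills user-constant offsets)."""
        ev = Event("e", "u", "high_stress_work", 3 * HOUR, 4 * HOUR)
        w1 = _flat_windows(hr=63.0)
        b1 = _mk_baseline(60.0, 60.0, 50.0, 50.0)
        out1 = bin_event_deviation(w1, ev, b1)
        c = 7.5
        w2 = _flat_windows(hr=63.0 + c)
        b2 = _mk_baseline(60.0 + c, 60.0 + c, 50.0, 50.0)
        out2 = bin_event_deviation(w2, ev, b2)
        pd.testing.assert_series_equal(
            out1["delta_hr_bpm"], out2["delta_hr_bpm"]
        )


def _binned(values, labels=None):
    labels = labels if labels is not None else POST_LABELS[: len(values)]
    return pd.DataFrame({
        "bin_label": labels,
        "delta_hr_bpm": values,
        "delta_hrv_ms": values,
    })


class TestEventAUC:
    def test_zero_curve(self):
        assert event_auc(_binned([0.0] * 10)) == (0.0, 0.0)

    def test_rectangle(self):
        auc_hr, _ = event_auc(_binned([2.0, 2.0]))
        assert auc_hr == pytest.approx(60.0)  # 2 * 30 min

    def test_hand_trapezoid(self):
        auc_hr, _ = event_auc(_binned([4.0, 2.0, 0.0]))
        assert auc_hr == pytest.approx((4 + 2) / 2 * 30 + (2 + 0) / 2 * 30)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=10)
        a1, _ = event_auc(_binned(vals))
        a3, _ = event_auc(_binned(3.0 * vals))
        assert a3 == pytest.approx(3.0 * a1)

    def test_missing_interior_bin_bridged_linearly(self):
        full = event_auc(_binned([4.0, 2.0, 0.0]))[0]
        gap = event_auc(
            _binned([4.0, 0.0], labels=["0-30", "60-90"])
        )[0]
        assert gap == pytest.approx((4 + 0) / 2 * 60)
        assert full == pytest.approx(120.0)  # three-point trapezoid oracle

    def test_single_bin_rejected(self):
        with pytest.raises(InsufficientDataError):
            event_auc(_binned([1.0]))
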