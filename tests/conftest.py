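import numpy as np
import pandas as pd
import pytest

from stresswear import CircadianProfile, MotionSeries, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def flat_profile():
    """Stationary profile: constant 60 bpm, target RMSSD 50 ms."""
    return CircadianProfile(
        hr_mesor_bpm=60.0, hr_amplitude_frac=0.0,
        hrv_mesor_ms=50.0, hrv_amplitude_frac=0.0,
        hr_trough_hour=3.0, hrv_peak_hour=6.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Two quiet users, one week, no missingness — shared across tests."""
    cfg = SimConfig(
        n_users=2, n_days=7, rng_seed=11, missing_day_prob=0.0,
        events_per_user={"run": 1, "high_stress_work": 1},
    )
    return simulate_cohort(cfg)


def quiet_motion(t0_s: float, t1_s: float, rate_hz: float = 1.0) -> MotionSeries:
    t = np.arange(t0_s, t1_s, 1.0 / rate_hz)
    return MotionSeries(t, np.zeros_like(t), rate_hz)


def synthetic_windows(
    hr: np.ndarray, hrv: np.ndarray, t: np.ndarray, valid=None
) -> pd.DataFrame:
    """Hand-built metric-window table for baseline/impact unit tests."""
    valid = np.ones(t.size, dtype=bool) if valid is None else valid
    return pd.DataFrame({
        "center_time_s": t,
        "hr_motionless_bpm": np.where(valid, hr, np.nan),
        "rmssd_ms": np.where(valid, hrv, np.nan),
        "n_beats": 300,
        "motionless": valid,
        "valid": valid,
    })
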