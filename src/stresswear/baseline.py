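"""Per-user circadian baselines and relative fractional difference profiles.

A user's baseline is the median motionless HR and RMSSD within each clock hour
over (at most) a 28-day span, pooled across days, together with the daily
medians over the whole span.  Users contribute only if they have at least 25
distinct days with valid data inside the span.

The relative fractional difference (RFD) expresses each hour relative to the
user's daily median.  Two formulations exist: the default ``hourly_over_daily``
(hour's median / daily median, so a typical hour sits near 1 and the plotted
rhythm has its natural orientation) and ``daily_over_hourly``, which inverts
the ratio.  Profiles can be aggregated on three axes: clock hour, hours from
sleep onset, and hours from wake onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .synthetic import DAY_S, HOUR_S, SleepSchedule

logger = logging.getLogger(__name__)

RFD_MODES = ("hourly_over_daily", "daily_over_hourly")

#: signed hour-offset ranges plotted for each alignment axis
SLEEP_ALIGN_RANGE = (-15.0, 9.0)
WAKE_ALIGN_RANGE = (-9.0, 15.0)


@dataclass(frozen=True)
class HourlyBaseline:
    """Per-user circadian baseline: 24 hourly medians plus daily medians."""

    user_id: str
    median_hr_bpm: np.ndarray  # shape (24,), NaN where the hour lacks data
    median_hrv_ms: np.ndarray
    n_windows: np.ndarray
    n_days_contributing: int
    daily_median_hr_bpm: float
    daily_median_hrv_ms: float


def hourly_medians(
    windows: pd.DataFrame,
    user_id: str = "",
    span_days: int = 28,
    min_days: int = 25,
    min_windows_per_hour: int = 3,
) -> HourlyBaseline | None:
    """Hour-of-day medians over the first ``span_days`` of a user's windows.

    Returns None (with a logged reason) when the user has fewer than
    ``min_days`` distinct days with valid windows inside the span — the
    cohort inclusion rule — rather than raising.  Hours backed by fewer than
    ``min_windows_per_hour`` valid windows yield NaN instead of an unstable
    median.
    """
    w = windows.loc[windows["valid"]]
    if w.empty:
        logger.info("user %s excluded: no valid windows", user_id)
        return None
    t = w["center_time_s"].to_numpy()
    day = np.floor_divide(t, DAY_S).astype(int)
    first_day = int(day.min())
    in_span = day < first_day + span_days
    w = w.loc[in_span]
    day = day[in_span]
    n_days = int(np.unique(day).size)
    if n_days < min_days:
        logger.info(
            "user %s excluded: %d data days < %d required within a %d-day span",
            user_id, n_days, min_days, span_days,
        )
        return None
    hour = np.floor_divide(w["center_time_s"].to_numpy(), HOUR_S).astype(int) % 24
    hr = w["hr_motionless_bpm"].to_numpy()
    hrv = w["rmssd_ms"].to_numpy()
    med_hr = np.full(24, np.nan)
    med_hrv = np.full(24, np.nan)
    counts = np.zeros(24, dtype=int)
    for h in range(24):
        sel = hour == h
        counts[h] = int(sel.sum())
        if counts[h] >= min_windows_per_hour:
            med_hr[h] = np.median(hr[sel])
            med_hrv[h] = np.median(hrv[sel])
    return HourlyBaseline(
        user_id=user_id,
        median_hr_bpm=med_hr,
        median_hrv_ms=med_hrv,
        n_windows=counts,
        n_days_contributing=n_days,
        daily_median_hr_bpm=float(np.median(hr)),
        daily_median_hrv_ms=float(np.median(hrv)),
    )


def _rfd(hourly: np.ndarray, daily: float, mode: str) -> np.ndarray:
    if mode not in RFD_MODES:
        raise ConfigurationError(f"rfd mode must be one of {RFD_MODES}")
    if daily == 0 or not np.isfinite(daily):
        raise ConfigurationError("daily median is zero/undefined; rfd undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "hourly_over_daily":
            return hourly / daily
        return np.where(hourly != 0, daily / hourly, np.nan)


def relative_fractional_difference(
    baseline: HourlyBaseline, mode: str = "hourly_over_daily"
) -> pd.DataFrame:
    """Clock-hour RFD profile with bin centers at half hours (0.5 ... 23.5)."""
    return pd.DataFrame({
        "user_id": baseline.user_id,
        "axis": "clock_hour",
        "bin_center_h": np.arange(24) + 0.5,
        "rfd_hr": _rfd(baseline.median_hr_bpm, baseline.daily_median_hr_bpm, mode),
        "rfd_hrv": _rfd(baseline.median_hrv_ms, baseline.daily_median_hrv_ms, mode),
        "n_windows": baseline.n_windows,
    })


def align_to_sleep_wake(
    windows: pd.DataFrame,
    sleep: SleepSchedule,
    baseline: HourlyBaseline,
    axis: str = "sleep",
    mode: str = "hourly_over_daily",
    min_windows_per_bin: int = 3,
) -> pd.DataFrame:
    """RFD profile on hours-from-sleep-onset (or wake-onset) axis.

    Each valid window is assigned a signed offset from the nearest onset of
    the chosen kind, binned half-open into 1-hour bins with half-hour centers
    (a window exactly at onset lands in bin +0.5).  Offsets outside the
    plotted range are dropped; per-bin medians are then divided by the user's
    daily median (or inverted under the verbatim mode).
    """
    if axis == "sleep":
        anchors = np.asarray(sleep.onset_s, float)
        lo, hi = SLEEP_ALIGN_RANGE
    elif axis == "wake":
        anchors = np.asarray(sleep.wake_s, float)
        lo, hi = WAKE_ALIGN_RANGE
    else:
        raise ConfigurationError("axis must be 'sleep' or 'wake'")
    if anchors.size == 0:
        raise ConfigurationError("sleep schedule has no episodes")
    w = windows.loc[windows["valid"]]
    t = w["center_time_s"].to_numpy()
    # nearest anchor (anchors are sorted: one primary episode per day)
    if anchors.size == 1:
        nearest = np.full(t.size, anchors[0])
    else:
        idx = np.clip(np.searchsorted(anchors, t), 1, anchors.size - 1)
        left, right = anchors[idx - 1], anchors[idx]
        nearest = np.where(np.abs(t - left) <= np.abs(right - t), left, right)
    offset_h = (t - nearest) / HOUR_S
    keep = (offset_h >= lo) & (offset_h < hi)
    offset_h = offset_h[keep]
    hr = w["hr_motionless_bpm"].to_numpy()[keep]
    hrv = w["rmssd_ms"].to_numpy()[keep]
    bins = np.floor(offset_h)  # half-open [k, k+1) -> center k + 0.5
    centers = np.arange(lo, hi) + 0.5
    med_hr = np.full(centers.size, np.nan)
    med_hrv = np.full(centers.size, np.nan)
    counts = np.zeros(centers.size, dtype=int)
    for i, c in enumerate(centers):
        sel = bins == np.floor(c)
        counts[i] = int(sel.sum())
        if counts[i] >= min_windows_per_bin:
            med_hr[i] = np.median(hr[sel])
            med_hrv[i] = np.median(hrv[sel])
    return pd.DataFrame({
        "user_id": baseline.user_id,
        "axis": f"hours_from_{axis}_onset",
        "bin_center_h": centers,
        "rfd_hr": _rfd(med_hr, baseline.daily_median_hr_bpm, mode),
        "rfd_hrv": _rfd(med_hrv, baseline.daily_median_hrv_ms, mode),
        "n_windows": counts,
    })


def cohort_rfd_profiles(
    per_user_windows: dict[str, pd.DataFrame],
    sleep_by_user: dict[str, SleepSchedule],
    mode: str = "hourly_over_daily",
    span_days: int = 28,
    min_days: int = 25,
) -> tuple[dict[str, HourlyBaseline], pd.DataFrame]:
    """Baselines plus stacked RFD profiles (all three axes) for a cohort.

    Users failing the inclusion rule are skipped (logged), not errors.
    """
    baselines: dict[str, HourlyBaseline] = {}
    frames: list[pd.DataFrame] = []
    for user_id, windows in per_user_windows.items():
        base = hourly_medians(
            windows, user_id=user_id, span_days=span_days, min_days=min_days
        )
        if base is None:
            continue
        baselines[user_id] = base
        frames.append(relative_fractional_difference(base, mode=mode))
        sched = sleep_by_user[user_id]
        frames.append(align_to_sleep_wake(windows, sched, base, "sleep", mode))
        frames.append(align_to_sleep_wake(windows, sched, base, "wake", mode))
    profiles = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["user_id", "axis", "bin_center_h", "rfd_hr", "rfd_hrv",
                     "n_windows"]
        )
    )
    return baselines, profiles
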