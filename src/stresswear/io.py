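"""Readers and writers for the on-disk CSV layout.

Per-user input directories hold ``rr.csv`` (timestamp_s, rr_ms), ``accel.csv``
(timestamp_s, magnitude_g), ``events.csv`` (event_id, type, load, start_s,
end_s) and ``sleep.csv`` (sleep_onset_s, wake_onset_s); all timestamps are
seconds from the cohort epoch.  Analysis outputs are headered CSV tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import BeatSeries, Event, MotionSeries, SleepSchedule


def read_user_dir(user_dir: str | Path):
    """Load one user's streams; returns (beats, motion, events, sleep)."""
    d = Path(user_dir)
    rr = pd.read_csv(d / "rr.csv")
    beats = BeatSeries(
        rr["timestamp_s"].to_numpy(dtype=float),
        rr["rr_ms"].to_numpy(dtype=float),
    )
    acc = pd.read_csv(d / "accel.csv")
    t = acc["timestamp_s"].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
    motion = MotionSeries(t, acc["magnitude_g"].to_numpy(dtype=float), rate)
    ev = pd.read_csv(d / "events.csv") if (d / "events.csv").exists() else None
    events: list[Event] = []
    if ev is not None and not ev.empty:
        for _, row in ev.iterrows():
            load = None if row["type"] != "run" else str(row["load"])
            events.append(Event(
                str(row["event_id"]), d.name, str(row["type"]),
                float(row["start_s"]), float(row["end_s"]), load,
            ))
    sl = pd.read_csv(d / "sleep.csv")
    sleep = SleepSchedule(
        sl["sleep_onset_s"].to_numpy(dtype=float),
        sl["wake_onset_s"].to_numpy(dtype=float),
    )
    return beats, motion, events, sleep


def list_user_dirs(cohort_dir: str | Path) -> list[Path]:
    return sorted(
        p for p in Path(cohort_dir).iterdir()
        if p.is_dir() and (p / "rr.csv").exists()
    )


def write_windows(windows: pd.DataFrame, path: str | Path) -> None:
    windows.to_csv(path, index=False, float_format="%.6f")


def read_windows(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["motionless"] = df["motionless"].astype(bool)
    df["valid"] = df["valid"].astype(bool)
    return df


def write_baselines(baselines: dict, path: str | Path) -> None:
    rows = []
    for user_id, b in baselines.items():
        for h in range(24):
            rows.append({
                "user_id": user_id,
                "hour_of_day": h,
                "median_hr_bpm": b.median_hr_bpm[h],
                "median_hrv_ms": b.median_hrv_ms[h],
                "n_windows": b.n_windows[h],
                "n_days_contributing": b.n_days_contributing,
                "daily_median_hr_bpm": b.daily_median_hr_bpm,
                "daily_median_hrv_ms": b.daily_median_hrv_ms,
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
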