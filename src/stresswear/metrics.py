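"""Motionless heart rate and RMSSD from RR + accelerometer streams.

The core operation is moving-block sub-sampling: 5-minute blocks advanced in
30-second steps over the recording.  Each block yields a heart-rate estimate
(60000 / mean RR, i.e. beats per elapsed time) and the RMSSD of its RR
intervals, and is flagged valid only when the accelerometer shows no motion
over the block, the block holds enough beats, and the HR estimate is
physiological.  Windows overlapping a logged run are always invalid: motion
artifacts make photoplethysmography unusable during running.

All per-window quantities are computed from prefix sums, so a full 28-day
stream (~80k windows) reduces to a handful of vectorised array passes; a
naive per-window recomputation is used as the oracle in the test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .synthetic import BeatSeries, MotionSeries

WINDOW_COLUMNS = [
    "center_time_s",
    "hr_motionless_bpm",
    "rmssd_ms",
    "n_beats",
    "motionless",
    "valid",
]


def rmssd(rr_ms: Sequence[float]) -> float:
    """Root-mean-square of successive RR-interval differences (ms)."""
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        raise InsufficientDataError("rmssd requires at least 2 RR intervals")
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d * d)))


def mean_hr(rr_ms: Sequence[float]) -> float:
    """Epoch heart rate in bpm: 60000 / mean(RR), i.e. beats per elapsed time
    (not the mean of instantaneous 60000/RR values)."""
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 1:
        raise InsufficientDataError("mean_hr requires at least 1 RR interval")
    return float(60000.0 / rr.mean())


def is_motionless(
    magnitude_g: Sequence[float],
    threshold_g: float,
    rest_level_g: float = 0.0,
    max_exceed_frac: float = 0.0,
) -> bool:
    """True iff the fraction of samples deviating from the rest level by more
    than ``threshold_g`` is at most ``max_exceed_frac`` (default: none)."""
    mag = np.asarray(magnitude_g, dtype=float)
    if mag.size == 0:
        raise InsufficientDataError("is_motionless requires a non-empty block")
    frac = np.mean(np.abs(mag - rest_level_g) > threshold_g)
    return bool(frac <= max_exceed_frac)


def _exclusion_mask(
    starts: np.ndarray,
    ends: np.ndarray,
    intervals: Iterable[tuple[float, float]],
) -> np.ndarray:
    """Windows [start, end) overlapping any closed interval [s, e]."""
    excluded = np.zeros(starts.size, dtype=bool)
    for s, e in intervals:
        excluded |= (starts <= e) & (ends > s)
    return excluded


def compute_metric_windows(
    beats: BeatSeries,
    motion: MotionSeries,
    step_s: float = 30.0,
    block_s: float = 300.0,
    min_beats: int = 100,
    threshold_g: float = 0.05,
    rest_level_g: float = 0.0,
    max_exceed_frac: float = 0.0,
    hr_range_bpm: tuple[float, float] = (25.0, 220.0),
    exclusion_intervals: Iterable[tuple[float, float]] | None = None,
    span: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Moving-block HR_motionless / RMSSD table.

    Windows tile the common span of both streams at ``step_s`` spacing; a
    window with center ``c`` uses beats with time in ``[c - block_s/2,
    c + block_s/2)`` (half-open, so adjacent blocks never double-count a
    beat).  Invalid windows keep their flags but carry NaN metrics.

    ``exclusion_intervals`` (e.g. run activities) invalidate every window
    whose block overlaps them, regardless of the accelerometer.
    """
    bt, rr = beats.beat_time_s, beats.rr_ms
    mt, mag = motion.sample_time_s, motion.magnitude_g
    if span is not None:
        t0, t1 = span
    else:
        if bt.size == 0 or mt.size == 0:
            return pd.DataFrame(columns=WINDOW_COLUMNS)
        t0 = max(bt[0], mt[0])
        t1 = min(bt[-1], mt[-1])
    half = block_s / 2.0
    first_center = t0 + half
    if first_center + half > t1 + 1e-9:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    centers = np.arange(first_center, t1 - half + 1e-9, step_s)
    starts = centers - half
    ends = centers + half

    # beats per window via prefix sums over the sorted beat stream
    i0 = np.searchsorted(bt, starts, side="left")
    i1 = np.searchsorted(bt, ends, side="left")
    n = (i1 - i0).astype(int)
    cs_rr = np.concatenate(([0.0], np.cumsum(rr)))
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_rr = np.where(n > 0, (cs_rr[i1] - cs_rr[i0]) / np.maximum(n, 1), np.nan)
        hr = 60000.0 / mean_rr

    # squared successive differences fully inside each window
    d2 = np.diff(rr) ** 2 if rr.size >= 2 else np.empty(0)
    cs_d2 = np.concatenate(([0.0], np.cumsum(d2)))
    ndiff = np.maximum(n - 1, 0)
    hi = np.maximum(i1 - 1, i0)
    ss = cs_d2[hi] - cs_d2[i0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rmssd_vals = np.where(ndiff > 0, np.sqrt(ss / np.maximum(ndiff, 1)), np.nan)

    # motion gating: fraction of exceeding samples per block
    exceed = (np.abs(mag - rest_level_g) > threshold_g).astype(float)
    cs_ex = np.concatenate(([0.0], np.cumsum(exceed)))
    j0 = np.searchsorted(mt, starts, side="left")
    j1 = np.searchsorted(mt, ends, side="left")
    nm = (j1 - j0).astype(int)
    frac = np.where(nm > 0, (cs_ex[j1] - cs_ex[j0]) / np.maximum(nm, 1), np.inf)
    motionless = frac <= max_exceed_frac

    valid = (
        motionless
        & (n >= min_beats)
        & (hr >= hr_range_bpm[0])
        & (hr <= hr_range_bpm[1])
    )
    if exclusion_intervals is not None:
        valid &= ~_exclusion_mask(starts, ends, exclusion_intervals)
    valid &= np.isfinite(hr) & np.isfinite(rmssd_vals)

    hr_out = np.where(valid, hr, np.nan)
    rmssd_out = np.where(valid, rmssd_vals, np.nan)
    return pd.DataFrame({
        "center_time_s": centers,
        "hr_motionless_bpm": hr_out,
        "rmssd_ms": rmssd_out,
        "n_beats": n,
        "motionless": motionless,
        "valid": valid,
    })


def windows_for_user(user, **kwargs) -> pd.DataFrame:
    """Metric windows for one simulated/loaded user, excluding run intervals."""
    runs = [(e.start_s, e.end_s) for e in user.events if e.type == "run"]
    return compute_metric_windows(
        user.beats, user.motion, exclusion_intervals=runs, **kwargs
    )
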