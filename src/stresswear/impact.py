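"""Event-aligned deviations of motionless HR and RMSSD, and dose summaries.

For each logged event (run or high-stress work) the valid metric windows are
aggregated into 30-minute bins: a single "Pre" bin covering the 30 minutes
before the start, a "During" bin over the event itself (high-stress work only;
running is motion-contaminated), and ten post-event bins ("0-30" ... "270-300"
minutes after the event ends).  Each bin mean is double-normalized: first the
user's hourly baseline median for the bin's clock hour is subtracted
(time-of-day correction), then the Pre value is subtracted, so a bin measures
the event-attributable deviation and Pre is identically zero.  The sign
convention is post minus pre: HR elevated after exercise is positive, HRV
suppression is negative.

Run load is classified by a documented heart-rate-reserve surrogate: each
during-run HR sample is mapped to a %HRR zone weight (0-5), the weights are
summed as weight-minutes, and score thresholds split light / moderate /
vigorous.

The per-event response magnitude is summarized by the trapezoidal area under
the binned deviation curve (baseline 0), in bpm·min or ms·min.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .baseline import HourlyBaseline
from .errors import InsufficientDataError
from .synthetic import HOUR_S, Event

logger = logging.getLogger(__name__)

BIN_MIN = 30.0
N_POST_BINS = 10
POST_LABELS = [f"{30 * k}-{30 * (k + 1)}" for k in range(N_POST_BINS)]
POST_CENTERS_MIN = np.arange(N_POST_BINS) * BIN_MIN + BIN_MIN / 2.0  # 15 ... 285

#: %HRR zone edges and their per-minute weights
HRR_ZONE_EDGES = (0.5, 0.6, 0.7, 0.8, 0.9)
HRR_ZONE_WEIGHTS = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
LOAD_SCORE_THRESHOLDS = (60.0, 180.0)  # light < 60 <= moderate <= 180 < vigorous


def classify_run_load(
    run_hr_bpm: Sequence[float],
    hr_max_bpm: float,
    hr_rest_bpm: float,
    minutes_per_sample: float = 1.0,
    score_thresholds: tuple[float, float] = LOAD_SCORE_THRESHOLDS,
) -> str:
    """Light/moderate/vigorous from time-in-zone weight-minutes (%HRR zones)."""
    hr = np.asarray(run_hr_bpm, dtype=float)
    if hr.size == 0:
        raise InsufficientDataError("run has no HR samples; unclassifiable")
    if hr_max_bpm <= hr_rest_bpm:
        raise ValueError("hr_max_bpm must exceed hr_rest_bpm")
    pct_hrr = (hr - hr_rest_bpm) / (hr_max_bpm - hr_rest_bpm)
    weights = np.asarray(HRR_ZONE_WEIGHTS)[
        np.searchsorted(HRR_ZONE_EDGES, pct_hrr, side="right")
    ]
    score = float(np.sum(weights) * minutes_per_sample)
    lo, hi = score_thresholds
    if score < lo:
        return "light"
    if score <= hi:
        return "moderate"
    return "vigorous"


def _bin_mean(
    windows: pd.DataFrame, start_s: float, end_s: float
) -> tuple[float, float, int]:
    """Mean HR/HRV of valid windows with center in [start_s, end_s)."""
    t = windows["center_time_s"].to_numpy()
    sel = windows["valid"].to_numpy() & (t >= start_s) & (t < end_s)
    n = int(sel.sum())
    if n == 0:
        return np.nan, np.nan, 0
    return (
        float(windows.loc[sel, "hr_motionless_bpm"].mean()),
        float(windows.loc[sel, "rmssd_ms"].mean()),
        n,
    )


def _hourly_norm(baseline: HourlyBaseline, center_s: float) -> tuple[float, float]:
    """Baseline medians for the clock hour containing the bin center."""
    hour = int(center_s // HOUR_S) % 24
    return (
        float(baseline.median_hr_bpm[hour]),
        float(baseline.median_hrv_ms[hour]),
    )


def bin_event_deviation(
    windows: pd.DataFrame,
    event: Event,
    baseline: HourlyBaseline,
    other_events: Sequence[Event] = (),
    exclude_contaminated: bool = True,
) -> pd.DataFrame | None:
    """Double-normalized 30-min bin deviations for one event.

    Returns None (logged) when the Pre window has no valid metric windows or
    the hourly baseline is undefined at the Pre hour — the event cannot be
    normalized.  Bins with no valid windows are omitted rows, never zeros.
    With ``exclude_contaminated``, bins overlapping another logged event's
    interval are dropped.
    """
    rows: list[dict] = []
    spans: list[tuple[str, float, float]] = [
        ("Pre", event.start_s - BIN_MIN * 60.0, event.start_s)
    ]
    if event.type == "high_stress_work":
        spans.append(("During", event.start_s, event.end_s))
    for k, label in enumerate(POST_LABELS):
        spans.append(
            (label, event.end_s + k * BIN_MIN * 60.0,
             event.end_s + (k + 1) * BIN_MIN * 60.0)
        )

    pre_hr = pre_hrv = None
    for label, s, e in spans:
        if exclude_contaminated and label != "Pre":
            # bins [s, e) overlapping the other event's closed interval
            contaminated = any(
                o.event_id != event.event_id and s <= o.end_s and e > o.start_s
                for o in other_events
            )
            if contaminated:
                continue
        hr, hrv, n = _bin_mean(windows, s, e)
        if n == 0:
            if label == "Pre":
                logger.info("event %s excluded: no valid Pre windows", event.event_id)
                return None
            continue
        base_hr, base_hrv = _hourly_norm(baseline, (s + e) / 2.0)
        if not (np.isfinite(base_hr) and np.isfinite(base_hrv)):
            if label == "Pre":
                logger.info(
                    "event %s excluded: baseline undefined at Pre hour",
                    event.event_id,
                )
                return None
            continue
        norm_hr = hr - base_hr
        norm_hrv = hrv - base_hrv
        if label == "Pre":
            pre_hr, pre_hrv = norm_hr, norm_hrv
        rows.append({
            "event_id": event.event_id,
            "user_id": event.user_id,
            "type": event.type,
            "load": event.load if event.load is not None else "n/a",
            "bin_label": label,
            "delta_hr_bpm": norm_hr - pre_hr,  # post - pre sign convention
            "delta_hrv_ms": norm_hrv - pre_hrv,
            "n_windows": n,
        })
    return pd.DataFrame(rows)


def event_auc(binned: pd.DataFrame) -> tuple[float, float]:
    """Trapezoidal AUC of the post-event deviation curve, baseline 0.

    Integrates over bin centers (15, 45, ..., 285 min); missing interior bins
    are bridged linearly by the trapezoid itself.  Requires at least two
    non-missing post-event bins.
    """
    post = binned.loc[binned["bin_label"].isin(POST_LABELS)]
    if len(post) < 2:
        raise InsufficientDataError("event_auc requires >= 2 post-event bins")
    order = {lab: i for i, lab in enumerate(POST_LABELS)}
    idx = post["bin_label"].map(order).to_numpy()
    sort = np.argsort(idx)
    centers = POST_CENTERS_MIN[idx[sort]]
    auc_hr = float(np.trapezoid(post["delta_hr_bpm"].to_numpy()[sort], centers))
    auc_hrv = float(np.trapezoid(post["delta_hrv_ms"].to_numpy()[sort], centers))
    return auc_hr, auc_hrv


def cohort_event_tables(
    per_user_windows: dict[str, pd.DataFrame],
    events_by_user: dict[str, Sequence[Event]],
    baselines: dict[str, HourlyBaseline],
    exclude_contaminated: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binned deviations and per-event AUCs for a whole cohort.

    Events of users without a baseline (inclusion failures) are skipped, as
    are events without a usable Pre bin or with fewer than two post bins.
    """
    bin_frames: list[pd.DataFrame] = []
    auc_rows: list[dict] = []
    for user_id, events in events_by_user.items():
        baseline = baselines.get(user_id)
        if baseline is None:
            continue
        windows = per_user_windows[user_id]
        for event in events:
            binned = bin_event_deviation(
                windows, event, baseline,
                other_events=events,
                exclude_contaminated=exclude_contaminated,
            )
            if binned is None or binned.empty:
                continue
            bin_frames.append(binned)
            try:
                auc_hr, auc_hrv = event_auc(binned)
            except InsufficientDataError:
                logger.info("event %s excluded from AUC: <2 post bins",
                            event.event_id)
                continue
            auc_rows.append({
                "event_id": event.event_id,
                "user_id": user_id,
                "type": event.type,
                "load": event.load if event.load is not None else "n/a",
                "auc_hr_bpm_min": auc_hr,
                "auc_hrv_ms_min": auc_hrv,
            })
    bins = (
        pd.concat(bin_frames, ignore_index=True)
        if bin_frames
        else pd.DataFrame(
            columns=["event_id", "user_id", "type", "load", "bin_label",
                     "delta_hr_bpm", "delta_hrv_ms", "n_windows"]
        )
    )
    aucs = pd.DataFrame(
        auc_rows,
        columns=["event_id", "user_id", "type", "load",
                 "auc_hr_bpm_min", "auc_hrv_ms_min"],
    )
    return bins, aucs
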