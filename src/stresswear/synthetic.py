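"""Synthetic free-living wearable-data generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: per-user
beat-to-beat (RR) interval streams with circadian rhythms in heart rate and
HRV anchored to a sleep schedule, an accelerometer-magnitude stream with rest
noise, fidget bouts and high-motion exercise, logged activity events (runs and
high-stress work) with exponentially decaying post-event HR elevation and HRV
suppression, and whole-day missingness.

The generator is the oracle for the analysis: every simulated cohort carries a
:class:`GroundTruth` with the analytic circadian curves and injected response
kinetics, so parameter recovery can be tested end to end.

Model
-----
Heart rate and HRV are single-harmonic sinusoids of clock time, phased to the
sleep schedule: HR reaches its minimum mid-sleep and RMSSD its maximum in late
sleep.  Beats are event-driven: beat ``i`` falls at ``t_{i-1} + RR_i / 1000``
with ``RR_i = 60000 / HR(t) + eps_i`` where the white noise ``eps_i`` has
standard deviation ``HRV(t) / sqrt(2)`` so that the theoretical RMSSD of the
noise equals the HRV target (for independent noise, RMSSD = sigma * sqrt(2)).
Stressor responses add ``+dHR * exp(-(t - t_end)/tau_hr)`` to HR and subtract
``dHRV * exp(-(t - t_end)/tau_hrv)`` from HRV after an event ends (and, for
high-stress work, a constant offset during the event); HRV is floored at 1 ms.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
spawning, one child stream per user and per stream kind, so modules can be
regenerated independently and deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ConfigurationError

HOUR_S = 3600.0
DAY_S = 86400.0
SQRT2 = np.sqrt(2.0)

#: Fraction of the sleep episode after onset at which HRV peaks ("late sleep").
HRV_PEAK_SLEEP_FRAC = 0.85

EVENT_TYPES = ("run", "high_stress_work")
RUN_LOADS = ("light", "moderate", "vigorous")


# ---------------------------------------------------------------------------
# response kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseParams:
    """Stressor response kinetics for one event type/load.

    ``delta_hr_bpm`` / ``delta_hrv_ms`` are the post-event amplitudes of the
    exponential HR elevation and HRV suppression with time constants
    ``tau_hr_min`` / ``tau_hrv_min``.  ``during_delta_hr_bpm`` /
    ``during_delta_hrv_ms`` are constant offsets applied while the event is in
    progress (exercise heart rate for runs; the stress offset itself for
    high-stress work).  ``duration_min`` is the typical event duration used by
    the scheduler.
    """

    delta_hr_bpm: float
    delta_hrv_ms: float
    tau_hr_min: float
    tau_hrv_min: float
    during_delta_hr_bpm: float = 0.0
    during_delta_hrv_ms: float = 0.0
    duration_min: float = 45.0


# Defaults emulate the dose structure of logged running loads (light runs
# barely perturb resting physiology; vigorous runs elevate HR by several bpm
# for hours and suppress RMSSD into the next several hours) and a sustained
# but milder psychological stressor.  During-run HR offsets put average
# exercise HR near 43 / 65 / 73 %HRR for light / moderate / vigorous.
DEFAULT_RESPONSE_PARAMS: dict[str, ResponseParams] = {
    "run:light": ResponseParams(0.5, 1.0, 45.0, 60.0, 52.0, -40.0, 26.0),
    "run:moderate": ResponseParams(4.0, 12.0, 90.0, 150.0, 81.0, -45.0, 44.0),
    "run:vigorous": ResponseParams(7.0, 22.0, 100.0, 180.0, 91.0, -50.0, 84.0),
    "high_stress_work": ResponseParams(3.0, 8.0, 45.0, 120.0, 3.0, -8.0, 115.0),
}


def response_key(event_type: str, load: str | None) -> str:
    return f"{event_type}:{load}" if event_type == "run" else event_type


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Cohort-level generator configuration.

    Defaults describe a realistic small observational cohort: 28 days of
    continuous wear, resting HR around 65 bpm with a ~7% circadian swing,
    RMSSD around 55 ms with a ~25% swing, sleep 23:00-07:00, a handful of
    logged runs and high-stress work events per user, and a 5% chance that a
    whole day of data is missing.
    """

    n_users: int = 20
    n_days: int = 28
    accel_rate_hz: float = 1.0
    hr_mesor_bpm: float = 65.0
    hr_mesor_sd_bpm: float = 3.0
    hr_circ_amplitude_frac: float = 0.07
    hrv_mesor_ms: float = 55.0
    hrv_mesor_sd_ms: float = 8.0
    hrv_circ_amplitude_frac: float = 0.25
    sleep_onset_hour: float = 23.0
    sleep_duration_h: float = 8.0
    events_per_user: dict[str, int] = field(
        default_factory=lambda: {"run": 3, "high_stress_work": 2}
    )
    response_params: dict[str, ResponseParams] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_PARAMS)
    )
    missing_day_prob: float = 0.05
    rng_seed: int = 0
    # motion model
    rest_sigma_g: float = 0.01
    fidget_rate_per_h: float = 2.0
    fidget_duration_s: tuple[float, float] = (20.0, 90.0)
    fidget_magnitude_g: float = 0.3
    active_magnitude_g: float = 0.8
    # event scheduling: earliest/latest clock hour an event may start
    event_start_hours: tuple[float, float] = (9.0, 15.5)

    def validate(self) -> None:
        def positive(name: str) -> None:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")

        for name in (
            "n_users",
            "n_days",
            "accel_rate_hz",
            "hr_circ_amplitude_frac",
            "hrv_circ_amplitude_frac",
            "sleep_duration_h",
            "rest_sigma_g",
            "fidget_magnitude_g",
            "active_magnitude_g",
        ):
            positive(name)
        if not 30.0 <= self.hr_mesor_bpm <= 120.0:
            raise ConfigurationError("hr_mesor_bpm must lie in [30, 120]")
        if not 5.0 <= self.hrv_mesor_ms <= 200.0:
            raise ConfigurationError("hrv_mesor_ms must lie in [5, 200]")
        if not 0.0 <= self.missing_day_prob < 1.0:
            raise ConfigurationError("missing_day_prob must lie in [0, 1)")
        if not 0.0 <= self.sleep_onset_hour < 24.0:
            raise ConfigurationError("sleep_onset_hour must lie in [0, 24)")
        if self.hr_circ_amplitude_frac >= 1.0:
            raise ConfigurationError("hr_circ_amplitude_frac must be < 1")
        if self.hrv_circ_amplitude_frac >= 1.0:
            raise ConfigurationError("hrv_circ_amplitude_frac must be < 1")
        if self.fidget_rate_per_h < 0:
            raise ConfigurationError("fidget_rate_per_h must be non-negative")
        for etype, n in self.events_per_user.items():
            if etype not in EVENT_TYPES:
                raise ConfigurationError(f"events_per_user: unknown type {etype!r}")
            if n < 0:
                raise ConfigurationError(f"events_per_user[{etype!r}] must be >= 0")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Event:
    event_id: str
    user_id: str
    type: str
    start_s: float
    end_s: float
    load: str | None = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ConfigurationError("event end_s must exceed start_s")
        if (self.load is not None) != (self.type == "run"):
            raise ConfigurationError("load is defined iff type == 'run'")


@dataclass(frozen=True)
class SleepSchedule:
    """Primary sleep episodes as parallel onset/wake arrays (seconds)."""

    onset_s: np.ndarray
    wake_s: np.ndarray


@dataclass(frozen=True)
class CircadianProfile:
    """One user's analytic HR/HRV curves plus injected stressor responses.

    ``hr_trough_hour`` is the clock hour of the HR minimum (mid-sleep) and
    ``hrv_peak_hour`` the clock hour of the RMSSD maximum (late sleep).
    """

    hr_mesor_bpm: float
    hr_amplitude_frac: float
    hrv_mesor_ms: float
    hrv_amplitude_frac: float
    hr_trough_hour: float
    hrv_peak_hour: float
    hrv_floor_ms: float = 1.0
    responses: tuple[tuple[Event, ResponseParams], ...] = ()

    def base_hr(self, t_s: np.ndarray) -> np.ndarray:
        phase = 2.0 * np.pi * (t_s / HOUR_S - self.hr_trough_hour) / 24.0
        return self.hr_mesor_bpm * (1.0 - self.hr_amplitude_frac * np.cos(phase))

    def base_hrv(self, t_s: np.ndarray) -> np.ndarray:
        phase = 2.0 * np.pi * (t_s / HOUR_S - self.hrv_peak_hour) / 24.0
        return self.hrv_mesor_ms * (1.0 + self.hrv_amplitude_frac * np.cos(phase))

    def _response_offsets(self, t_s: np.ndarray, which: str) -> np.ndarray:
        """Summed stressor offsets for one channel ("hr" or "hrv").

        Time arrays in this package are nondecreasing, enabling O(log n)
        slice lookups and truncation of the exponential tails where the
        offset falls below 1e-13 of its amplitude; unsorted input falls back
        to boolean masks.
        """
        out = np.zeros_like(t_s, dtype=float)
        if t_s.size == 0:
            return out
        if t_s.size < 2:
            sorted_t = True
        elif t_s.size <= 100_000:
            sorted_t = bool(np.all(t_s[1:] >= t_s[:-1]))
        else:
            # long streams are beat/sample times, nondecreasing by
            # construction; spot-check a stride rather than a full diff
            sorted_t = bool(np.all(t_s[::4096][1:] >= t_s[::4096][:-1]))
        for event, p in self.responses:
            if which == "hr":
                during_delta, delta, tau = (
                    p.during_delta_hr_bpm, p.delta_hr_bpm, p.tau_hr_min
                )
            else:
                during_delta, delta, tau = (
                    p.during_delta_hrv_ms, -p.delta_hrv_ms, p.tau_hrv_min
                )
            if sorted_t:
                i0 = np.searchsorted(t_s, event.start_s, side="left")
                i1 = np.searchsorted(t_s, event.end_s, side="right")
                if during_delta != 0.0:
                    out[i0:i1] += during_delta
                if delta != 0.0:
                    j1 = np.searchsorted(
                        t_s, event.end_s + 30.0 * 60.0 * tau, side="right"
                    )
                    dt_min = (t_s[i1:j1] - event.end_s) / 60.0
                    out[i1:j1] += delta * np.exp(-dt_min / tau)
            else:
                if during_delta != 0.0:
                    during = (t_s >= event.start_s) & (t_s <= event.end_s)
                    out[during] += during_delta
                if delta != 0.0:
                    post = t_s > event.end_s
                    dt_min = (t_s[post] - event.end_s) / 60.0
                    out[post] += delta * np.exp(-dt_min / tau)
        return out

    def hr(self, t_s: np.ndarray) -> np.ndarray:
        t_s = np.asarray(t_s, dtype=float)
        out = self.base_hr(t_s)
        if self.responses:
            out = out + self._response_offsets(t_s, "hr")
        return out

    def hrv(self, t_s: np.ndarray) -> np.ndarray:
        t_s = np.asarray(t_s, dtype=float)
        out = self.base_hrv(t_s)
        if self.responses:
            # the physiological floor guards response-driven suppression; a
            # degenerate zero-HRV base (noiseless test streams) stays exact
            out = np.maximum(out + self._response_offsets(t_s, "hrv"),
                             self.hrv_floor_ms)
        return out


@dataclass(frozen=True)
class BeatSeries:
    """Timestamped RR intervals; beat i occurs at ``beat_time_s[i]`` and
    closes the interval ``rr_ms[i]``.  Carries the generating profile so
    responses can be injected by exact noise decomposition."""

    beat_time_s: np.ndarray
    rr_ms: np.ndarray
    profile: CircadianProfile | None = None
    t0_s: float = 0.0


@dataclass(frozen=True)
class MotionSeries:
    sample_time_s: np.ndarray
    magnitude_g: np.ndarray
    rate_hz: float


@dataclass(frozen=True)
class UserData:
    user_id: str
    beats: BeatSeries
    motion: MotionSeries
    events: tuple[Event, ...]
    sleep: SleepSchedule
    present_days: np.ndarray  # sorted day indices with data


@dataclass(frozen=True)
class GroundTruth:
    """Realized generator parameters for recovery testing.

    ``users`` maps user_id to the analytic circadian summary (true hourly
    median HR/HRV over each clock hour, daily medians, mesors); ``events``
    holds one record per simulated event with its response parameters and the
    analytic 30-min bin-averaged post-event offsets.
    """

    users: dict[str, dict]
    events: list[dict]


@dataclass(frozen=True)
class CohortDataset:
    config: SimConfig
    users: tuple[UserData, ...]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# stream generators
# ---------------------------------------------------------------------------


def simulate_rr_stream(
    profile: CircadianProfile,
    t0_s: float,
    t1_s: float,
    rng: np.random.Generator,
    noiseless: bool = False,
) -> BeatSeries:
    """Generate an event-driven RR stream over ``[t0_s, t1_s]``.

    The beat-time recursion ``t_i = t_{i-1} + RR_i(t)/1000`` is solved by
    fixed-point iteration (three passes); HR varies on hour scales so the
    iteration converges far below millisecond accuracy.  Noise is white with
    ``sigma(t) = HRV(t)/sqrt(2)`` so the noise RMSSD matches the HRV target.
    """
    if t1_s <= t0_s:
        raise ConfigurationError("stream span must be positive (t1_s > t0_s)")
    # cumulative beat count N(t) = integral of HR(t)/60 on a 15-s grid; HR
    # varies on hour scales (circadian) or tens of minutes (responses), so
    # trapezoidal integration at this resolution is accurate to << 1 beat
    grid = np.arange(t0_s, t1_s + 15.0, 15.0)
    hr_grid = profile.hr(grid)
    if np.any(hr_grid <= 0):
        raise ConfigurationError("hr profile is non-positive within the span")
    rate = hr_grid / 60.0  # beats per second
    n_cum = np.concatenate(
        ([0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0 * np.diff(grid)))
    )
    n = int(np.floor(n_cum[-1]))
    # noiseless previous-beat times by inverting N(t); the stream is
    # event-driven, each RR evaluated at the preceding beat's time
    t_prev = np.interp(np.arange(n), n_cum, grid)
    rr = 60000.0 / profile.hr(t_prev)
    if not noiseless:
        rr = rr + rng.standard_normal(n) * (profile.hrv(t_prev) / SQRT2)
        np.maximum(rr, 1.0, out=rr)  # RR intervals stay strictly positive
    t_beat = t0_s + np.cumsum(rr) / 1000.0
    keep = t_beat <= t1_s
    return BeatSeries(t_beat[keep], rr[keep], profile=profile, t0_s=t0_s)


def inject_event_response(
    beats: BeatSeries, event: Event, params: ResponseParams
) -> BeatSeries:
    """Return a new BeatSeries with the event's HR/HRV response injected.

    Recovers each beat's noise term from the stream's own generating profile
    (``eps_i = rr_i - 60000/HR(t_i)``), rescales it by the new/old HRV ratio,
    and re-accumulates beat times under the perturbed HR curve.  A null
    response returns the stream unchanged.
    """
    if beats.profile is None:
        raise ConfigurationError("beats must carry a generating profile")
    if event.end_s > beats.beat_time_s[-1] + 1.0:
        raise ConfigurationError("event end_s lies beyond the stream span")
    if params.delta_hr_bpm == 0.0 and params.delta_hrv_ms == 0.0 and (
        params.during_delta_hr_bpm == 0.0 and params.during_delta_hrv_ms == 0.0
    ):
        return beats

    old = beats.profile
    new_profile = replace(old, responses=old.responses + ((event, params),))
    t_prev = np.concatenate(([beats.t0_s], beats.beat_time_s[:-1]))
    new_hr = new_profile.hr(t_prev)
    if np.any(new_hr < 25.0) or np.any(new_hr > 220.0):
        raise ConfigurationError(
            "response_params drive HR outside [25, 220] bpm"
        )
    old_hrv = old.hrv(t_prev)
    eps = beats.rr_ms - 60000.0 / old.hr(t_prev)
    # re-derive the stream under the perturbed curves; beat times shift when
    # RR changes, so iterate the event-driven recursion to a fixed point
    t_beat = beats.beat_time_s
    for _ in range(3):
        hrv_ratio = np.divide(
            new_profile.hrv(t_prev), old_hrv,
            out=np.ones_like(old_hrv), where=old_hrv > 0,
        )
        rr = 60000.0 / new_profile.hr(t_prev) + eps * hrv_ratio
        np.maximum(rr, 1.0, out=rr)
        t_beat = beats.t0_s + np.cumsum(rr) / 1000.0
        t_prev = np.concatenate(([beats.t0_s], t_beat[:-1]))
    return BeatSeries(t_beat, rr, profile=new_profile, t0_s=beats.t0_s)


def simulate_motion_stream(
    t0_s: float,
    t1_s: float,
    events: tuple[Event, ...],
    rng: np.random.Generator,
    rate_hz: float = 1.0,
    rest_sigma_g: float = 0.01,
    fidget_rate_per_h: float = 2.0,
    fidget_duration_s: tuple[float, float] = (20.0, 90.0),
    fidget_magnitude_g: float = 0.3,
    active_magnitude_g: float = 0.8,
) -> MotionSeries:
    """Accelerometer-magnitude stream: half-normal rest noise, Poisson fidget
    bouts, and saturated high motion over every run interval (high-stress work
    is sedentary so its windows stay motionless)."""
    for e in events:
        if e.start_s < t0_s or e.end_s > t1_s:
            raise ConfigurationError("event lies outside the motion span")
    t = np.arange(t0_s, t1_s, 1.0 / rate_hz)
    mag = np.abs(rng.normal(0.0, rest_sigma_g, size=t.size))

    hours = (t1_s - t0_s) / HOUR_S
    n_fidgets = rng.poisson(fidget_rate_per_h * hours)
    if n_fidgets > 0:
        starts = rng.uniform(t0_s, t1_s, size=n_fidgets)
        durs = rng.uniform(*fidget_duration_s, size=n_fidgets)
        for s, d in zip(starts, durs):
            i0, i1 = np.searchsorted(t, [s, s + d])
            if i1 > i0:
                mag[i0:i1] = fidget_magnitude_g + np.abs(
                    rng.normal(0.0, rest_sigma_g, size=i1 - i0)
                )
    for e in events:
        if e.type != "run":
            continue
        i0 = np.searchsorted(t, e.start_s, side="left")
        i1 = np.searchsorted(t, e.end_s, side="right")
        mag[i0:i1] = active_magnitude_g + np.abs(
            rng.normal(0.0, rest_sigma_g, size=max(i1 - i0, 0))
        )
    return MotionSeries(t, mag, rate_hz)


# ---------------------------------------------------------------------------
# ground-truth summaries
# ---------------------------------------------------------------------------


def _hourly_curve_medians(fn: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """True per-clock-hour medians of an analytic curve (fine time grid)."""
    out = np.empty(24)
    for h in range(24):
        grid = np.linspace(h * HOUR_S, (h + 1) * HOUR_S, 601)
        out[h] = float(np.median(fn(grid)))
    return out


def _daily_curve_median(fn: Callable[[np.ndarray], np.ndarray]) -> float:
    grid = np.linspace(0.0, DAY_S, 24 * 601)
    return float(np.median(fn(grid)))


def analytic_bin_mean(delta: float, tau_min: float, n_bins: int = 10,
                      bin_min: float = 30.0) -> np.ndarray:
    """Bin-averaged value of ``delta * exp(-t/tau)`` over consecutive
    post-event bins: ``delta * tau/width * (e^(-t_k/tau) - e^(-t_{k+1}/tau))``."""
    edges = np.arange(n_bins + 1) * bin_min
    return delta * tau_min / bin_min * (
        np.exp(-edges[:-1] / tau_min) - np.exp(-edges[1:] / tau_min)
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _build_sleep_schedule(config: SimConfig) -> SleepSchedule:
    onsets, wakes = [], []
    span = config.n_days * DAY_S
    for d in range(-1, config.n_days):
        onset = d * DAY_S + config.sleep_onset_hour * HOUR_S
        wake = onset + config.sleep_duration_h * HOUR_S
        if wake > 0 and onset < span:
            onsets.append(onset)
            wakes.append(wake)
    return SleepSchedule(np.asarray(onsets, float), np.asarray(wakes, float))


def _schedule_events(
    config: SimConfig, user_id: str, present_days: np.ndarray,
    rng: np.random.Generator,
) -> list[Event]:
    """Place at most one event per present day, cycling run loads."""
    n_total = sum(config.events_per_user.values())
    if n_total > present_days.size:
        raise ConfigurationError(
            "events_per_user exceeds the number of days with data"
        )
    days = rng.permutation(present_days)[:n_total]
    events: list[Event] = []
    i = 0
    for etype in EVENT_TYPES:
        for k in range(config.events_per_user.get(etype, 0)):
            load = RUN_LOADS[k % len(RUN_LOADS)] if etype == "run" else None
            params = config.response_params[response_key(etype, load)]
            lo, hi = config.event_start_hours
            start = days[i] * DAY_S + rng.uniform(lo, hi) * HOUR_S
            end = start + params.duration_min * 60.0
            events.append(
                Event(f"{user_id}_e{i:03d}", user_id, etype, start, end, load)
            )
            i += 1
    events.sort(key=lambda e: e.start_s)
    return events


def _mask_missing_days(
    times: np.ndarray, missing: set[int]
) -> np.ndarray:
    if not missing:
        return np.ones(times.size, dtype=bool)
    day = np.floor_divide(times, DAY_S).astype(int)
    return ~np.isin(day, sorted(missing))


def simulate_cohort(config: SimConfig) -> CohortDataset:
    """Generate the full cohort deterministically from ``config.rng_seed``."""
    config.validate()
    root = np.random.SeedSequence(config.rng_seed)
    user_seeds = root.spawn(config.n_users)
    span = config.n_days * DAY_S
    sleep = _build_sleep_schedule(config)
    mid_sleep = config.sleep_onset_hour + config.sleep_duration_h / 2.0
    hrv_peak = config.sleep_onset_hour + HRV_PEAK_SLEEP_FRAC * config.sleep_duration_h

    users: list[UserData] = []
    gt_users: dict[str, dict] = {}
    gt_events: list[dict] = []
    for u, seed in enumerate(user_seeds):
        user_id = f"user_{u:03d}"
        # independent child streams: profile draw, missingness, scheduling,
        # beats, motion
        s_prof, s_miss, s_sched, s_beat, s_motion = (
            np.random.Generator(np.random.PCG64(s)) for s in seed.spawn(5)
        )
        hr_mesor = float(
            np.clip(
                s_prof.normal(config.hr_mesor_bpm, config.hr_mesor_sd_bpm),
                30.0, 120.0,
            )
        )
        hrv_mesor = float(
            np.clip(
                s_prof.normal(config.hrv_mesor_ms, config.hrv_mesor_sd_ms),
                5.0, 200.0,
            )
        )
        base_profile = CircadianProfile(
            hr_mesor_bpm=hr_mesor,
            hr_amplitude_frac=config.hr_circ_amplitude_frac,
            hrv_mesor_ms=hrv_mesor,
            hrv_amplitude_frac=config.hrv_circ_amplitude_frac,
            hr_trough_hour=mid_sleep % 24.0,
            hrv_peak_hour=hrv_peak % 24.0,
        )
        missing = {
            d for d in range(config.n_days)
            if s_miss.random() < config.missing_day_prob
        }
        present = np.asarray(sorted(set(range(config.n_days)) - missing), int)
        if present.size == 0:
            users.append(UserData(
                user_id,
                BeatSeries(np.empty(0), np.empty(0), base_profile),
                MotionSeries(np.empty(0), np.empty(0), config.accel_rate_hz),
                (), sleep, present,
            ))
            gt_users[user_id] = _user_truth(base_profile)
            continue
        events = _schedule_events(config, user_id, present, s_sched)
        responses = tuple(
            (e, config.response_params[response_key(e.type, e.load)])
            for e in events
        )
        profile = replace(base_profile, responses=responses)
        beats = simulate_rr_stream(profile, 0.0, span, s_beat)
        motion = simulate_motion_stream(
            0.0, span, tuple(events), s_motion,
            rate_hz=config.accel_rate_hz,
            rest_sigma_g=config.rest_sigma_g,
            fidget_rate_per_h=config.fidget_rate_per_h,
            fidget_duration_s=config.fidget_duration_s,
            fidget_magnitude_g=config.fidget_magnitude_g,
            active_magnitude_g=config.active_magnitude_g,
        )
        bkeep = _mask_missing_days(beats.beat_time_s, missing)
        mkeep = _mask_missing_days(motion.sample_time_s, missing)
        beats = BeatSeries(
            beats.beat_time_s[bkeep], beats.rr_ms[bkeep], profile, beats.t0_s
        )
        motion = MotionSeries(
            motion.sample_time_s[mkeep], motion.magnitude_g[mkeep], motion.rate_hz
        )
        users.append(UserData(user_id, beats, motion, tuple(events), sleep, present))
        gt_users[user_id] = _user_truth(base_profile)
        for e in events:
            p = config.response_params[response_key(e.type, e.load)]
            gt_events.append({
                "event_id": e.event_id,
                "user_id": user_id,
                "type": e.type,
                "load": e.load,
                "start_s": e.start_s,
                "end_s": e.end_s,
                "delta_hr_bpm": p.delta_hr_bpm,
                "delta_hrv_ms": p.delta_hrv_ms,
                "tau_hr_min": p.tau_hr_min,
                "tau_hrv_min": p.tau_hrv_min,
                "during_delta_hr_bpm": p.during_delta_hr_bpm,
                "during_delta_hrv_ms": p.during_delta_hrv_ms,
                "bin_mean_delta_hr": analytic_bin_mean(
                    p.delta_hr_bpm, p.tau_hr_min
                ).tolist(),
                "bin_mean_delta_hrv": (-analytic_bin_mean(
                    p.delta_hrv_ms, p.tau_hrv_min
                )).tolist(),
            })
    return CohortDataset(config, tuple(users), GroundTruth(gt_users, gt_events))


def _user_truth(profile: CircadianProfile) -> dict:
    return {
        "hr_mesor_bpm": profile.hr_mesor_bpm,
        "hrv_mesor_ms": profile.hrv_mesor_ms,
        "hr_trough_hour": profile.hr_trough_hour,
        "hrv_peak_hour": profile.hrv_peak_hour,
        "hourly_median_hr": _hourly_curve_medians(profile.base_hr).tolist(),
        "hourly_median_hrv": _hourly_curve_medians(profile.base_hrv).tolist(),
        "daily_median_hr": _daily_curve_median(profile.base_hr),
        "daily_median_hrv": _daily_curve_median(profile.base_hrv),
    }


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> None:
    """Write one directory per user (rr.csv, accel.csv, events.csv, sleep.csv)
    plus a cohort-level ground_truth.json.  Timestamps are seconds from the
    cohort epoch."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for user in dataset.users:
        udir = out / user.user_id
        udir.mkdir(exist_ok=True)
        # round to microsecond / micro-g precision; the default float repr of
        # rounded values writes far faster than per-value format strings
        pd.DataFrame({
            "timestamp_s": np.round(user.beats.beat_time_s, 6),
            "rr_ms": np.round(user.beats.rr_ms, 6),
        }).to_csv(udir / "rr.csv", index=False)
        pd.DataFrame({
            "timestamp_s": np.round(user.motion.sample_time_s, 6),
            "magnitude_g": np.round(user.motion.magnitude_g, 6),
        }).to_csv(udir / "accel.csv", index=False)
        ev_cols = ["event_id", "type", "load", "start_s", "end_s"]
        pd.DataFrame(
            [
                {
                    "event_id": e.event_id,
                    "type": e.type,
                    "load": e.load if e.load is not None else "n/a",
                    "start_s": e.start_s,
                    "end_s": e.end_s,
                }
                for e in user.events
            ],
            columns=ev_cols,
        ).to_csv(udir / "events.csv", index=False)
        pd.DataFrame({
            "sleep_onset_s": user.sleep.onset_s,
            "wake_onset_s": user.sleep.wake_s,
        }).to_csv(udir / "sleep.csv", index=False, float_format="%.1f")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {"users": dataset.ground_truth.users,
             "events": dataset.ground_truth.events},
            fh, indent=1,
        )
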