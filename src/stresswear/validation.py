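"""Parameter-recovery experiments: run the full pipeline on simulated cohorts
and compare what it recovers against the generator's ground truth.

These are the package's validation workloads — circadian slope recovery,
post-event response-duration recovery, null calibration of the Dunnett
procedure, and dose-response ordering — shaped so a single call runs one
experiment end to end (simulate -> metric windows -> baselines -> event bins
-> inference) and returns both the estimate and the analytic truth it should
recover.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .baseline import cohort_rfd_profiles
from .impact import POST_LABELS, cohort_event_tables
from .inference import DEFAULT_KNOTS_HR_CLOCK, dunnett_vs_pre, fit_linear_spline
from .metrics import windows_for_user
from .synthetic import (
    CircadianProfile,
    ResponseParams,
    SimConfig,
    analytic_bin_mean,
    simulate_cohort,
)


def analytic_rfd_hr(config: SimConfig) -> np.ndarray:
    """Noise-free clock-hour RFD profile implied by the generator's HR curve
    (hourly medians of the sinusoid divided by its daily median); identical
    for every user because the RFD is scale-free."""
    from .synthetic import _daily_curve_median, _hourly_curve_medians

    mid_sleep = (config.sleep_onset_hour + config.sleep_duration_h / 2.0) % 24.0
    prof = CircadianProfile(
        hr_mesor_bpm=config.hr_mesor_bpm,
        hr_amplitude_frac=config.hr_circ_amplitude_frac,
        hrv_mesor_ms=config.hrv_mesor_ms,
        hrv_amplitude_frac=config.hrv_circ_amplitude_frac,
        hr_trough_hour=mid_sleep,
        hrv_peak_hour=(config.sleep_onset_hour + 0.85 * config.sleep_duration_h)
        % 24.0,
    )
    hourly = _hourly_curve_medians(prof.base_hr)
    return hourly / _daily_curve_median(prof.base_hr)


def circadian_recovery_seed(
    seed: int,
    n_users: int = 50,
    n_days: int = 14,
    amplitude: float = 0.05,
    knots: tuple[float, ...] = DEFAULT_KNOTS_HR_CLOCK,
) -> dict:
    """One seed of the circadian-slope recovery experiment.

    Simulates a quiet cohort (no stressor events) with the given HR circadian
    amplitude, runs the metric/baseline stages, fits the diurnal spline to the
    pooled clock-hour HR RFD profile, and fits the same spline to the
    generator's analytic RFD curve.  Returns fitted slopes, their SEs, the
    analytic slopes, and whether every segment landed within 2 SE.
    """
    cfg = SimConfig(
        n_users=n_users,
        n_days=n_days,
        hr_circ_amplitude_frac=amplitude,
        events_per_user={},
        rng_seed=seed,
    )
    ds = simulate_cohort(cfg)
    per_user = {u.user_id: windows_for_user(u) for u in ds.users}
    sleep = {u.user_id: u.sleep for u in ds.users}
    min_days = max(2, int(round(n_days * 25 / 28)))  # inclusion rule, scaled
    _, profiles = cohort_rfd_profiles(
        per_user, sleep, span_days=n_days, min_days=min_days
    )
    clock = profiles.loc[profiles["axis"] == "clock_hour"].dropna(
        subset=["rfd_hr"]
    )
    fit = fit_linear_spline(
        clock["bin_center_h"].to_numpy(), clock["rfd_hr"].to_numpy(), knots
    )
    truth_fit = fit_linear_spline(
        np.arange(24) + 0.5, analytic_rfd_hr(cfg), knots
    )
    within = np.abs(
        fit.segment_slopes_beta - truth_fit.segment_slopes_beta
    ) <= 2.0 * fit.segment_se
    return {
        "beta_hat": fit.segment_slopes_beta,
        "se": fit.segment_se,
        "beta_true": truth_fit.segment_slopes_beta,
        "all_within_2se": bool(np.all(within)),
        "n_users_included": int(clock["user_id"].nunique()),
    }


def _event_cohort_config(
    seed: int,
    n_users: int,
    n_days: int,
    events_per_user: dict[str, int],
    run_response: ResponseParams | None = None,
    hsw_response: ResponseParams | None = None,
) -> SimConfig:
    cfg = SimConfig(
        n_users=n_users, n_days=n_days, events_per_user=events_per_user,
        rng_seed=seed,
    )
    params = dict(cfg.response_params)
    if run_response is not None:
        for load in ("light", "moderate", "vigorous"):
            base = params[f"run:{load}"]
            params[f"run:{load}"] = replace(
                run_response,
                during_delta_hr_bpm=base.during_delta_hr_bpm,
                during_delta_hrv_ms=base.during_delta_hrv_ms,
                duration_min=base.duration_min,
            )
    if hsw_response is not None:
        params["high_stress_work"] = hsw_response
    cfg.response_params = params
    return cfg


def run_event_pipeline(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """simulate -> windows -> baselines -> event tables for one cohort."""
    ds = simulate_cohort(cfg)
    per_user = {u.user_id: windows_for_user(u) for u in ds.users}
    sleep = {u.user_id: u.sleep for u in ds.users}
    min_days = max(2, int(round(cfg.n_days * 25 / 28)))
    baselines, _ = cohort_rfd_profiles(
        per_user, sleep, span_days=cfg.n_days, min_days=min_days
    )
    events_by_user = {u.user_id: u.events for u in ds.users}
    bins, aucs = cohort_event_tables(per_user, events_by_user, baselines)
    truth = {
        "ground_truth": ds.ground_truth,
        "n_users_included": len(baselines),
    }
    return bins, aucs, truth


def event_duration_recovery(
    seed: int,
    delta_hr_bpm: float = 6.0,
    tau_hr_min: float = 90.0,
    n_users: int = 50,
    events_per_user: int = 10,
    n_days: int = 14,
    alpha: float = 0.05,
) -> dict:
    """Recover the duration of an injected post-run HR elevation.

    All runs share the same exponential response; the Dunnett-significant
    bins are compared against the analytic detectability crossing: a bin is
    detectable when the injected bin-averaged offset exceeds the Dunnett
    critical value times the empirical per-event noise / sqrt(n_events).
    """
    run_resp = ResponseParams(
        delta_hr_bpm=delta_hr_bpm, delta_hrv_ms=15.0,
        tau_hr_min=tau_hr_min, tau_hrv_min=150.0,
    )
    cfg = _event_cohort_config(
        seed, n_users, n_days, {"run": events_per_user}, run_response=run_resp
    )
    bins, _, _ = run_event_pipeline(cfg)
    run_bins = bins.loc[bins["type"] == "run"]
    res = dunnett_vs_pre(run_bins, metric="delta_hr_bpm", alpha=alpha)
    res = res.set_index("bin_label").reindex(POST_LABELS)

    mu = analytic_bin_mean(delta_hr_bpm, tau_hr_min, n_bins=len(POST_LABELS))
    # empirical per-event noise around the injected bin means
    sd = np.full(len(POST_LABELS), np.nan)
    n_ev = np.zeros(len(POST_LABELS))
    for k, lab in enumerate(POST_LABELS):
        vals = run_bins.loc[run_bins["bin_label"] == lab, "delta_hr_bpm"]
        n_ev[k] = len(vals)
        if len(vals) > 1:
            sd[k] = float(np.std(vals - mu[k], ddof=1))
    # Dunnett critical value for the family (independent-contrast form)
    from .inference import dunnett_critical_value

    df = float(res["df"].dropna().iloc[0])
    crit = dunnett_critical_value(len(POST_LABELS), df, alpha=alpha)
    detectable = mu > crit * sd / np.sqrt(np.maximum(n_ev, 1))
    sig = res["significant"].fillna(False).to_numpy(dtype=bool)
    last_sig = int(np.max(np.nonzero(sig)[0])) if sig.any() else -1
    last_detectable = (
        int(np.max(np.nonzero(detectable)[0])) if detectable.any() else -1
    )
    return {
        "dunnett": res,
        "n_events": int(run_bins["event_id"].nunique()),
        "last_significant_bin": last_sig,
        "last_detectable_bin": last_detectable,
        "bin_means_analytic": mu,
        "per_event_sd": sd,
        "critical_t": crit,
        "elevation_duration_min": 30.0 * (last_sig + 1),
    }


def null_replicate_any_significant(
    seed: int,
    n_users: int = 4,
    n_days: int = 6,
    events_per_user: int = 4,
    alpha: float = 0.05,
) -> bool:
    """One null-cohort replicate: True if any post-event HR bin reaches
    Dunnett significance when no response was injected (family-wise error)."""
    null_resp = ResponseParams(0.0, 0.0, 60.0, 60.0, 0.0, 0.0, 115.0)
    cfg = _event_cohort_config(
        seed, n_users, n_days, {"high_stress_work": events_per_user},
        hsw_response=null_resp,
    )
    cfg.missing_day_prob = 0.0
    bins, _, _ = run_event_pipeline(cfg)
    res = dunnett_vs_pre(
        bins.loc[bins["type"] == "high_stress_work"],
        metric="delta_hr_bpm", alpha=alpha,
    )
    return bool(res["significant"].any())


def dose_response_seed(
    seed: int,
    effects: dict[str, float] | None = None,
    n_users_per_group: int = 12,
    sigma: float = 30.0,
    alpha: float = 0.05,
) -> dict:
    """Tukey recovery of ordered AUC effects across run-load groups.

    Per-event AUCs are drawn around the stated group effects (bpm.min) with
    Gaussian noise, mimicking the per-event AUC table the impact stage
    produces; recovery means every pair significant with the correct sign.
    """
    from .inference import tukey_auc_groups

    effects = effects or {"light": 0.0, "moderate": 120.0, "vigorous": 240.0}
    rng = np.random.default_rng(seed)
    rows = []
    for load, mu in effects.items():
        for u in range(n_users_per_group):
            rows.append({
                "user_id": f"{load}_u{u}",
                "event_id": f"{load}_e{u}",
                "load": load,
                "auc_hr_bpm_min": mu + rng.normal(0.0, sigma),
            })
    res = tukey_auc_groups(pd.DataFrame(rows), alpha=alpha)
    order = {"light": 0, "moderate": 1, "vigorous": 2}
    correct_sign = all(
        (r["estimate"] < 0) == (order[r["group_a"]] < order[r["group_b"]])
        for _, r in res.iterrows()
    )
    return {
        "tukey": res,
        "all_significant": bool(res["significant"].all()),
        "correct_ordering": correct_sign,
    }
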