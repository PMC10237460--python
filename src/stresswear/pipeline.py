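"""End-to-end orchestration: simulate -> metrics -> baseline -> impact -> infer.

A single structured YAML config drives all stages; ``run_pipeline`` executes
them in order on a simulated (or pre-existing) cohort directory and writes a
run manifest with the config snapshot, seed, package version and SHA-256
digests of every output, so a rerun with the same config is verifiably
identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baseline import cohort_rfd_profiles
from .errors import ConfigurationError, InferenceError
from .impact import cohort_event_tables
from .inference import (
    DEFAULT_KNOTS_HR_CLOCK,
    DEFAULT_KNOTS_HRV_CLOCK,
    dunnett_vs_pre,
    fit_linear_spline,
    tukey_auc_groups,
)
from .io import list_user_dirs, read_user_dir, write_baselines, write_windows
from .metrics import compute_metric_windows
from .synthetic import ResponseParams, SimConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

ANALYSIS_DEFAULTS = {
    "step_s": 30.0,
    "block_s": 300.0,
    "min_beats": 100,
    "threshold_g": 0.05,
    "max_exceed_frac": 0.0,
    "rfd_mode": "hourly_over_daily",
    "span_days": 28,
    "min_days": 25,
    "alpha": 0.05,
    "exclude_contaminated": True,
    "average_within_user": True,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config root must be a mapping")
    return cfg


def sim_config_from_dict(d: dict, seed: int | None = None) -> SimConfig:
    d = dict(d or {})
    if "response_params" in d:
        d["response_params"] = {
            key: ResponseParams(**val) for key, val in d["response_params"].items()
        }
    if "events_per_user" in d:
        d["events_per_user"] = {k: int(v) for k, v in d["events_per_user"].items()}
    for tup_field in ("fidget_duration_s", "event_start_hours"):
        if tup_field in d:
            d[tup_field] = tuple(d[tup_field])
    try:
        cfg = SimConfig(**d)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    if seed is not None:
        cfg.rng_seed = int(seed)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_cohort_dir(cohort_dir: Path, out_dir: Path, params: dict) -> list[Path]:
    """Run metrics/baseline/impact/inference stages on a cohort directory."""
    p = {**ANALYSIS_DEFAULTS, **params}
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    per_user_windows: dict[str, pd.DataFrame] = {}
    sleep_by_user: dict = {}
    events_by_user: dict = {}
    for udir in list_user_dirs(cohort_dir):
        beats, motion, events, sleep = read_user_dir(udir)
        runs = [(e.start_s, e.end_s) for e in events if e.type == "run"]
        windows = compute_metric_windows(
            beats, motion,
            step_s=p["step_s"], block_s=p["block_s"], min_beats=p["min_beats"],
            threshold_g=p["threshold_g"], max_exceed_frac=p["max_exceed_frac"],
            exclusion_intervals=runs,
        )
        per_user_windows[udir.name] = windows
        sleep_by_user[udir.name] = sleep
        events_by_user[udir.name] = events
        wpath = out_dir / f"windows_{udir.name}.csv"
        write_windows(windows, wpath)
        outputs.append(wpath)

    baselines, profiles = cohort_rfd_profiles(
        per_user_windows, sleep_by_user,
        mode=p["rfd_mode"], span_days=p["span_days"], min_days=p["min_days"],
    )
    bpath = out_dir / "baseline.csv"
    write_baselines(baselines, bpath)
    ppath = out_dir / "rfd_profiles.csv"
    profiles.to_csv(ppath, index=False, float_format="%.6f")
    outputs += [bpath, ppath]

    bins, aucs = cohort_event_tables(
        per_user_windows, events_by_user, baselines,
        exclude_contaminated=p["exclude_contaminated"],
    )
    binpath = out_dir / "event_bins.csv"
    bins.to_csv(binpath, index=False, float_format="%.6f")
    aucpath = out_dir / "event_auc.csv"
    aucs.to_csv(aucpath, index=False, float_format="%.6f")
    outputs += [binpath, aucpath]

    outputs += run_inference(profiles, bins, aucs, out_dir, p)
    return outputs


def run_inference(
    profiles: pd.DataFrame, bins: pd.DataFrame, aucs: pd.DataFrame,
    out_dir: Path, p: dict,
) -> list[Path]:
    outputs: list[Path] = []
    summary_lines: list[str] = []

    # diurnal splines on the cohort clock-hour profiles
    spline_rows = []
    clock = profiles.loc[profiles["axis"] == "clock_hour"].dropna(
        subset=["rfd_hr", "rfd_hrv"]
    )
    for metric, col, knots in (
        ("rfd_hr", "rfd_hr", DEFAULT_KNOTS_HR_CLOCK),
        ("rfd_hrv", "rfd_hrv", DEFAULT_KNOTS_HRV_CLOCK),
    ):
        if clock.empty:
            continue
        try:
            fit = fit_linear_spline(
                clock["bin_center_h"].to_numpy(), clock[col].to_numpy(), knots
            )
        except InferenceError as exc:
            logger.warning("spline fit skipped for %s: %s", metric, exc)
            continue
        for j in range(len(fit.segment_slopes_beta)):
            spline_rows.append({
                "metric": metric,
                "segment_start_h": fit.knots_h[j],
                "segment_end_h": fit.knots_h[j + 1],
                "beta": fit.segment_slopes_beta[j],
                "se": fit.segment_se[j],
                "p_value": fit.segment_p_values[j],
            })
        summary_lines.append(f"# diurnal spline segments: {metric}")
        for r in spline_rows:
            if r["metric"] == metric:
                summary_lines.append(
                    f"  {r['segment_start_h']:5.1f}-{r['segment_end_h']:5.1f} h  "
                    f"beta={r['beta']:+.4f}  p={r['p_value']:.3g}"
                )
    spath = out_dir / "spline_fits.csv"
    pd.DataFrame(spline_rows).to_csv(spath, index=False, float_format="%.6g")
    outputs.append(spath)

    # Dunnett vs Pre per event group and metric
    dunnett_rows = []
    group_keys = []
    if not bins.empty:
        for (etype, load), sub in bins.groupby(["type", "load"]):
            group_keys.append((etype, load, sub))
    for etype, load, sub in group_keys:
        for metric in ("delta_hr_bpm", "delta_hrv_ms"):
            try:
                res = dunnett_vs_pre(sub, metric=metric, alpha=p["alpha"])
            except InferenceError as exc:
                logger.warning(
                    "dunnett skipped for %s/%s %s: %s", etype, load, metric, exc
                )
                continue
            res.insert(0, "metric", metric)
            res.insert(0, "load", load)
            res.insert(0, "type", etype)
            dunnett_rows.append(res)
            summary_lines.append(f"# dunnett vs Pre: {etype}/{load} {metric}")
            for _, r in res.iterrows():
                summary_lines.append(
                    f"  {r['bin_label']:>8}  est={r['estimate']:+.4f}  "
                    f"p_adj={r['p_adjusted']:.3g}"
                    f"{'  *' if r['significant'] else ''}"
                )
    dpath = out_dir / "dunnett.csv"
    (pd.concat(dunnett_rows, ignore_index=True) if dunnett_rows
     else pd.DataFrame()).to_csv(dpath, index=False, float_format="%.6g")
    outputs.append(dpath)

    # Tukey across run loads
    tukey_frames = []
    run_auc = aucs.loc[aucs["type"] == "run"] if not aucs.empty else aucs
    for metric in ("auc_hr_bpm_min", "auc_hrv_ms_min"):
        if run_auc.empty:
            break
        try:
            res = tukey_auc_groups(
                run_auc, metric=metric,
                average_within_user=p["average_within_user"], alpha=p["alpha"],
            )
        except InferenceError as exc:
            logger.warning("tukey skipped for %s: %s", metric, exc)
            continue
        res.insert(0, "metric", metric)
        tukey_frames.append(res)
        summary_lines.append(f"# tukey across run loads: {metric}")
        for _, r in res.iterrows():
            summary_lines.append(
                f"  {r['group_a']} vs {r['group_b']}  est={r['estimate']:+.2f}  "
                f"p_adj={r['p_adjusted']:.3g}{'  *' if r['significant'] else ''}"
            )
    tpath = out_dir / "tukey.csv"
    (pd.concat(tukey_frames, ignore_index=True) if tukey_frames
     else pd.DataFrame()).to_csv(tpath, index=False, float_format="%.6g")
    outputs.append(tpath)

    sumpath = out_dir / "summary.txt"
    sumpath.write_text("\n".join(summary_lines) + "\n")
    outputs.append(sumpath)
    return outputs


def run_pipeline(
    config_path: str | Path | None = None,
    out_dir: str | Path = "stresswear_run",
    seed: int | None = None,
    config: dict | None = None,
) -> dict:
    """Execute all stages from one config; returns the run manifest."""
    t_start = time.time()
    cfg = config if config is not None else (
        load_config(config_path) if config_path else {}
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_cfg = cfg.get("data", {})
    analysis_cfg = cfg.get("analysis", {})

    if "cohort_dir" in data_cfg:
        cohort_dir = Path(data_cfg["cohort_dir"])
        if not cohort_dir.is_dir() or not list_user_dirs(cohort_dir):
            raise ConfigurationError(
                f"cohort_dir {cohort_dir} missing or holds no user directories"
            )
    else:
        sim_cfg = sim_config_from_dict(cfg.get("simulate", {}), seed=seed)
        cohort_dir = out / "cohort"
        dataset = simulate_cohort(sim_cfg)
        write_cohort(dataset, cohort_dir)
        logger.info("simulated %d users into %s", sim_cfg.n_users, cohort_dir)

    outputs = analyze_cohort_dir(cohort_dir, out / "analysis", analysis_cfg)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config": _jsonable(cfg),
        "started_unix": t_start,
        "elapsed_s": time.time() - t_start,
        "outputs": {str(f.relative_to(out)): _sha256(f) for f in sorted(outputs)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
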