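# stresswear

Quantify how physical and psychological stressors perturb cardiovascular
physiology in free-living wearable data.

Consumer wrist wearables deliver continuous photoplethysmography-derived
beat-to-beat (RR) intervals and accelerometry. From these, two resting
markers can be computed around daily life events: motionless heart rate
(HR<sub>motionless</sub>, beats per minute in accelerometer-quiet periods)
and heart-rate variability as RMSSD (root-mean-square of successive RR
differences, ms). Both carry strong circadian rhythms, so raw post-event
values confound time-of-day with the event itself. `stresswear` implements a
complete, tested pipeline that:

1. computes HR<sub>motionless</sub> and RMSSD by **moving-block
   sub-sampling** (5-minute blocks, 30-second steps) with strict motion
   gating of each block;
2. builds per-user **circadian baselines** — the median of each metric per
   clock hour over a 28-day span (users need ≥ 25 days of data) — and
   relative fractional difference (RFD) profiles by clock hour and by hours
   from sleep/wake onset;
3. **double-normalizes** 30-minute bins around logged events (runs,
   high-stress work): each bin mean minus the hourly baseline median, minus
   the pre-event value, so a bin measures event-attributable deviation;
4. classifies run load (light / moderate / vigorous) with a documented
   %heart-rate-reserve time-in-zone surrogate score;
5. runs the **statistical layer**: continuous piecewise-linear (spline) fits
   to diurnal RFD profiles, linear mixed models (random intercept per user)
   with Dunnett many-to-one comparison of each post-event bin against the
   pre-event bin, and Tukey HSD on per-event trapezoidal AUCs across run
   loads.

Because raw cohort data from such devices is proprietary, the package ships
a first-class **synthetic-data generator** with known ground truth: sinusoidal
circadian HR/HRV anchored to a sleep schedule, white RR noise calibrated so
the stream's RMSSD hits the target (RMSSD = σ·√2 for white noise),
accelerometer rest noise / fidgets / exercise motion, and exponentially
decaying post-event responses. Every analysis stage is validated by
recovering the generator's parameters.

## Worked example

```python
from stresswear import run_pipeline

config = {
    "simulate": {"n_users": 5, "n_days": 28,
                 "events_per_user": {"run": 3, "high_stress_work": 2}},
    "analysis": {},
}
run_pipeline(config=config, out_dir="demo_run", seed=42)
print(open("demo_run/analysis/summary.txt").read())
```

Excerpts of the summary this run prints:

```
# diurnal spline segments: rfd_hr
    0.5-  4.5 h  beta=-0.0035  p=1.35e-08
    4.5- 13.5 h  beta=+0.0164  p=1.16e-102
   13.5- 19.5 h  beta=-0.0066  p=1.18e-40
   19.5- 23.5 h  beta=-0.0204  p=4.54e-62
# dunnett vs Pre: run/vigorous delta_hr_bpm
      0-30  est=+7.1171  p_adj=1.65e-22  *
     30-60  est=+4.7389  p_adj=6.74e-17  *
     ...
   180-210  est=+1.1158  p_adj=0.0103  *
   210-240  est=+0.8792  p_adj=0.0711
# tukey across run loads: auc_hr_bpm_min
  light vs moderate  est=-287.11  p_adj=1.31e-05  *
  light vs vigorous  est=-600.10  p_adj=4.06e-09  *
  moderate vs vigorous  est=-312.99  p_adj=5.4e-06  *
```

Reading: the diurnal RFD of motionless HR falls overnight, rises through the
morning (β = +0.0164 fractional units per hour) and falls again in the
evening; after a vigorous run HR<sub>motionless</sub> stays significantly
elevated for 180–210 minutes (last Dunnett-significant bin) while a light
run barely registers; and the post-run HR AUC ordering light < moderate <
vigorous is recovered with all Tukey pairs significant.

The same stages are available as a CLI:

```bash
stresswear simulate --config docs/example_config.yaml --out cohort/ --seed 7
stresswear metrics  --in cohort/user_000 --out windows_user_000.csv
stresswear run      --config docs/example_config.yaml --out full_run/ --seed 7
```

## Layout

- `src/stresswear/synthetic.py` — generator + ground truth
- `src/stresswear/metrics.py` — RMSSD, epoch HR, motion gating, windows
- `src/stresswear/baseline.py` — hourly medians, RFD, sleep/wake alignment
- `src/stresswear/impact.py` — event bins, load surrogate, trapezoid AUC
- `src/stresswear/inference.py` — splines, mixed-model Dunnett, Tukey HSD
- `src/stresswear/pipeline.py`, `cli.py` — orchestration, manifest, CLI
- `docs/methods.md` — modelling and statistical choices in detail
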