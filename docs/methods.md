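# Methods

## Problem and model

A stressor — a run, or a stretch of self-reported high-stress work — pushes
the autonomic nervous system toward sympathetic dominance: heart rate rises
and vagally mediated heart-rate variability (RMSSD) falls, and both recover
over minutes to hours after the stressor ends. In free-living wearable data
the measurement itself is only trustworthy at rest (photoplethysmography is
motion-sensitive), and resting heart rate and RMSSD carry circadian rhythms
comparable in size to the stressor effects. The pipeline therefore measures
*event-attributable* deviations: metrics are computed only in motionless
windows, corrected for the user's own time-of-day baseline, and re-based to
the 30 minutes immediately before the event.

## Signal metrics

- **RMSSD** over a block of RR intervals: `sqrt(mean((RR[i+1] - RR[i])^2))`
  (ms). At least two intervals are required.
- **Heart rate** per block: `60000 / mean(RR)` — beats per elapsed time (the
  conventional epoch estimator), *not* the mean of instantaneous `60000/RR`.
  The two differ for variable RR; the count-based form is used throughout.
- **Moving-block sub-sampling**: 5-minute blocks advanced by 30 s. Beat
  membership is half-open `[center - 150 s, center + 150 s)` so adjacent
  blocks never double-count a beat. A block is *valid* when (a) the
  accelerometer magnitude never deviates from the rest level by more than
  `threshold_g` (default 0.05 g; an exceedance-fraction tolerance exists for
  sensitivity analyses but defaults to all-or-nothing), (b) it holds at
  least 100 beats (≈ 20 bpm floor, forbidding degenerate RMSSD), and
  (c) the HR estimate is within 25–220 bpm. Blocks overlapping a logged run
  are always invalid regardless of the accelerometer, because running motion
  precludes reliable beat detection. Invalid blocks keep their flags but
  carry NaN metrics.
- All per-window quantities come from prefix sums (O(1) per window); the
  test suite checks exact agreement with a naive per-window recomputation.

The motion threshold is a declared free parameter of this pipeline, not a
reconstruction of any device vendor's internal artifact criterion.

## Circadian baseline and RFD

Per user, the baseline is the median valid-window HR and RMSSD within each
clock hour, pooled across at most 28 days; users with fewer than 25 distinct
data days in the span are excluded (inclusion rule), and hours with fewer
than 3 valid windows yield no baseline entry rather than an unstable median.
Pooling windows across days (rather than median-of-daily-medians) is the
default; the alternative is available behind a flag.

The relative fractional difference (RFD) expresses an hour against the
user's daily median. Two formulations are implemented because they are both
defensible readings of the quantity: the default `hourly_over_daily`
(hour ÷ day, so the plotted rhythm has its natural orientation and a typical
hour sits at 1) and the inverted `daily_over_hourly`. The default was chosen
because the inverted form flips the orientation of the diurnal rhythm
relative to how such profiles are conventionally plotted; both modes are
covered by tests and selectable in configuration.

Sleep/wake-aligned profiles assign each valid window a signed hour offset
from the nearest sleep (or wake) onset of that calendar day, binned
half-open `[k, k+1)` with half-hour centers — a window exactly at onset
falls in bin +0.5. Plotted ranges are −14.5…+8.5 h around sleep onset and
−8.5…+14.5 h around wake onset. Days without a sleep record contribute no
aligned windows. Naps are out of scope.

## Event impact

Bins: one *Pre* bin `[start − 30 min, start)`, a *During* bin over the event
(high-stress work only; runs are motion-contaminated), and ten 30-minute
post bins measured from the event *end* (0–300 min). Each bin mean of valid
windows is normalized by the hourly baseline median of the clock hour
containing the bin center (no interpolation — matching the baseline's hourly
resolution), then the Pre value is subtracted. The sign convention is
`post − pre`, so post-exercise HR elevation is positive and HRV suppression
negative. Pre is identically zero by construction. Bins with no valid
windows are omitted, never imputed as zero. Events without a usable Pre bin
are excluded with a logged reason. By default, bins overlapping another
logged event are dropped (contamination guard, flag-controlled); post-event
windows falling in sleep are kept — sleep windows are motionless and valid.

**Run-load surrogate.** Each during-run HR sample (motion included) is
mapped to a %heart-rate-reserve zone — `<50%: 0, 50–60: 1, 60–70: 2,
70–80: 3, 80–90: 4, ≥90: 5` — and the per-minute weights summed. Scores
< 60 are light, 60–180 moderate, > 180 vigorous. These thresholds are
calibrated so that easy / steady / hard simulated runs land in the intended
classes; they make no claim to reproduce any proprietary scoring.

**AUC.** The post-event deviation curve is integrated by the trapezoidal
rule over bin centers (15, 45, …, 285 min) with 0 as baseline; missing
interior bins are bridged linearly. Units: bpm·min or ms·min.

## Statistical layer

- **Diurnal splines**: continuous piecewise-linear least squares on a
  truncated-power basis, knots at configured bin centers (defaults
  {0.5, 4.5, 13.5, 19.5, 23.5} h for HR and {0.5, 6.5, 11.5, 17.5, 23.5} h
  for HRV). Each segment's slope β (fractional RFD per hour) gets a
  two-sided t-test via the coefficient contrast.
- **Dunnett vs Pre**: the deviation table is modelled with a linear mixed
  model with a fixed effect per bin and a random intercept per user — the
  minimal structure honouring repeated events within users. Because double
  normalization makes Pre identically zero, including the zero-variance Pre
  rows would deflate the residual variance and inflate type-I error; the
  model is therefore fit on the post-event (and During) bins only, and each
  bin mean is tested against zero with max-|T| (Dunnett) adjustment across
  bins, computed from the estimated fixed-effect correlation via the
  multivariate-t CDF. Degrees of freedom use a containment-style residual
  count (observations − bins − users), reported in the output. The test
  suite verifies the family-wise error on 500 null cohorts.
- **Tukey HSD on AUCs**: all-pairs comparison across light / moderate /
  vigorous. Per-event AUCs are averaged within user per group first (one
  value per user per group) to avoid pseudo-replication; a flag enables raw
  per-event mode.

Significance is α = 0.05 throughout; adjusted p-values are clipped to never
fall below the unadjusted ones.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
deliberately simple mechanisms:

- **Circadian shape**: single-harmonic sinusoids phased to the sleep
  schedule — HR minimum mid-sleep, RMSSD maximum late sleep (85% of the way
  through the episode). The analysis never assumes this functional form.
- **Beats**: event-driven; beat *i* occurs at `t[i-1] + RR[i]/1000` with
  `RR = 60000/HR(t) + ε`, ε white with σ(t) = HRV(t)/√2 so the noise RMSSD
  equals the HRV target. The self-referential beat-time recursion is solved
  by inverting the cumulative beat-count integral on a 15-second grid; HR
  varies on hour scales, so the error is far below a millisecond, and
  noiseless streams reproduce the analytic curve to < 0.001 bpm in windowed
  means.
- **Responses**: after an event, HR gains `+δ_HR · exp(−Δt/τ_HR)` and HRV
  loses `δ_HRV · exp(−Δt/τ_HRV)` (floored at 1 ms to stay physiological);
  high-stress work also applies its offset during the event, and runs apply
  a large constant during-run HR offset (exercise heart rate). Response
  injection into an existing stream recovers each beat's noise from the
  generating profile, rescales it by the new/old HRV ratio, and re-derives
  beat times by fixed-point iteration.
- **Motion**: half-normal rest noise (σ = 0.01 g), Poisson fidget bouts
  (2/h, 20–90 s, 0.3 g), and saturated motion (0.8 g) over every run so
  run windows are rejected. High-stress work is sedentary.
- **Missingness**: whole days are dropped independently with probability
  0.05 (intra-day gaps arise naturally from fidgets and events).
- **Randomness**: one root seed, split via `numpy.random.SeedSequence` into
  per-user child streams (profile draw, missingness, scheduling, beats,
  motion), so any stream can be regenerated independently and the whole
  cohort is bit-reproducible.

Default cohort parameters (28 days; resting HR 65 ± 3 bpm between users with
a 7% circadian amplitude; RMSSD 55 ± 8 ms with a 25% amplitude; sleep
23:00–07:00; run responses of 0.5/4/7 bpm and 1/12/22 ms for light /
moderate / vigorous with τ of 45–100 min (HR) and 60–180 min (HRV);
high-stress work +3 bpm / −8 ms, applied during and decaying after) are the
package's own choices of a realistic free-living cohort: no public
distributional description of such cohorts' circadian amplitudes or response
kinetics exists, so they are stated as configurable defaults rather than
estimates.

**What the generator does not emulate** — PPG waveform artifacts, ectopic
beats, autocorrelated HRV dynamics (the noise is white, making RMSSD = σ√2
exact), demographic covariates, naps, or irregular sleep. Passing tests
therefore demonstrate that the *pipeline* recovers known structure under its
own assumptions, not that those assumptions exhaust real data.

## Validation experiments and problem sizes

`stresswear.validation` runs four recovery experiments end to end; the test
suite and `scripts/acceptance.py` both call them. Sizes are chosen to keep
the full suite within a desktop-scale run while leaving comfortable
statistical margins:

- **Circadian slope recovery**: 20 seeds × 50 quiet users, 14-day spans
  (inclusion rule scaled proportionally, 12/14 days), HR amplitude 5%.
  Fitted spline slopes must land within 2 SE of the slopes obtained by
  fitting the same spline to the generator's analytic RFD curve in ≥ 90% of
  seeds.
- **Event-duration recovery**: 500 runs (50 users × 10) with δ_HR = 6 bpm,
  τ = 90 min. The last Dunnett-significant bin must fall within one bin of
  the analytic detectability crossing — the last bin whose injected
  bin-averaged offset `δ·(τ/30)·(e^(−t_k/τ) − e^(−t_{k+1}/τ))` exceeds the
  Dunnett critical value times the empirical per-event SD / √n.
- **Null calibration**: 500 replicate cohorts (4 users × 6 days × 4
  high-stress-work events with zero injected response; days scaled down
  because family-wise error does not depend on cohort length). The rate of
  any significant bin must not exceed 0.07 at nominal 0.05.
- **Dose-response**: per-event AUC tables with group effects 0 / 120 / 240
  bpm·min and σ = 30 noise; all three Tukey pairs significant and correctly
  ordered in ≥ 95% of 40 seeds.

## Numerical and edge-case choices

- Half-open conventions everywhere (windows, alignment bins, impact bins);
  boundary observations go to the right bin exactly once.
- Windows with zero beats or an empty motion block are invalid, not errors;
  empty streams yield empty tables.
- A degenerate HRV target of 0 is allowed (noiseless test streams); the
  1-ms HRV floor applies only to response-driven suppression.
- Mixed models are fit by Powell's method (REML), which tolerates the zero
  random-effect-variance boundary; Nelder–Mead is the fallback.
- The multivariate-t rectangle probabilities behind the Dunnett adjustment
  use a fixed internal QMC seed so p-values are reproducible.
- An all-zero deviation table short-circuits to "nothing significant"
  rather than fitting a singular model.

## Configuration

One YAML file drives every stage (see `docs/example_config.yaml`): a
`simulate:` block mirroring `SimConfig` (or `data: {cohort_dir: ...}` to
analyse existing per-user directories), and an `analysis:` block with the
window, baseline, impact and inference parameters (step/block lengths,
motion threshold, RFD mode, inclusion thresholds, α). CLI flags override
config values; every run writes a manifest with the config snapshot, seed,
package versions and SHA-256 digests of all outputs.

## Known limitations

- The RFD and deviation estimates inherit the hourly resolution of the
  baseline; sub-hour circadian structure is smoothed.
- Dunnett degrees of freedom use a containment approximation rather than
  Satterthwaite/Kenward–Roger; with hundreds of observations per bin the
  difference is negligible, and the null calibration test bounds the
  practical consequence.
- The load surrogate depends on user-supplied (or simulated) HR maxima and
  resting HR; misspecified reserves shift the class boundaries.
- Events whose post-window crosses midnight borrow the next day's baseline
  hours, which is intended behaviour but assumes day-stable baselines.
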