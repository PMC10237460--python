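# stresswear pipeline configuration
#
# Two top-level blocks:
#   simulate: generator parameters (omit and provide data.cohort_dir to
#             analyse an existing cohort of per-user directories instead)
#   analysis: window / baseline / impact / inference parameters
#
# Any field left out takes the package default shown here.

simulate:
  n_users: 5
  n_days: 28
  accel_rate_hz: 1.0
  hr_mesor_bpm: 65.0            # cohort mean resting HR (bpm)
  hr_mesor_sd_bpm: 3.0          # between-user SD
  hr_circ_amplitude_frac: 0.07  # circadian amplitude, fraction of mesor
  hrv_mesor_ms: 55.0            # cohort mean RMSSD (ms)
  hrv_mesor_sd_ms: 8.0
  hrv_circ_amplitude_frac: 0.25
  sleep_onset_hour: 23.0
  sleep_duration_h: 8.0
  missing_day_prob: 0.05        # whole-day dropout probability
  events_per_user:
    run: 3                      # loads cycle light -> moderate -> vigorous
    high_stress_work: 2
  # response_params may override the per-type/load kinetics, e.g.:
  # response_params:
  #   "run:vigorous": {delta_hr_bpm: 7.0, delta_hrv_ms: 22.0,
  #                    tau_hr_min: 100.0, tau_hrv_min: 180.0,
  #                    during_delta_hr_bpm: 91.0,
  #                    during_delta_hrv_ms: -50.0, duration_min: 84.0}

# data:
#   cohort_dir: path/to/cohort   # per-user dirs with rr.csv, accel.csv, ...

analysis:
  step_s: 30.0                  # moving-block step
  block_s: 300.0                # moving-block length
  min_beats: 100                # beats required per valid block
  threshold_g: 0.05             # motion gate on |magnitude - rest|
  max_exceed_frac: 0.0          # fraction of samples allowed over the gate
  rfd_mode: hourly_over_daily   # or daily_over_hourly (verbatim inverse)
  span_days: 28                 # baseline span
  min_days: 25                  # inclusion: distinct data days in span
  alpha: 0.05
  exclude_contaminated: true    # drop bins overlapping another event
  average_within_user: true     # Tukey on per-user mean AUCs
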