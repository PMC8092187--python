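# sstkit

A toolkit for stop-signal task (SST) studies of inhibitory control:

* **`task_design`** — randomized session sequences (go/stop trials, two
  stimulus categories, eight stimuli, color→key mapping) and the 1-up/1-down
  stop-signal-delay (SSD) staircase (start 200 ms, step 50 ms, clamped to
  [50, 900] ms, tracked separately per stimulus category).
* **`race_sim`** — synthetic cohorts under the independent race model:
  ex-Gaussian go finishing times, truncated-Gaussian stop latencies, go
  omissions, choice errors, and additive covariate effects (condition,
  overweight, age) on the latent parameters.
* **`ssrt_estimator`** — the integration method with replacement of go
  omissions: SSRT = go-RT quantile at the probability of responding given a
  stop signal (rank `ceil(p × n_go)`, 1-based) minus the mean SSD, computed
  per stimulus category.
* **`qc`** — consensus exclusion rules: missing behavioral data, implausible
  self-reported height, stopping probability outside [25%, 75%]
  (participant-level), and race-model violations (mean signal-respond RT ≥
  mean go RT; drops the affected per-category value only).
* **`cohort_analysis`** — overweight classification (BMI ≥ 25), a
  random-intercept mixed model with Wald F-tests (sum-to-zero coding,
  containment denominator df), BMI–SSRT product-moment correlation with
  Fisher-z CI and a MAD-based outlier sensitivity re-analysis, and a-priori
  power for the correlation test (exact sampling-density integration, plus
  the Fisher-z closed form).
* **`cli`/`io`** — a `sstkit` command-line pipeline over plain-CSV artifacts.

The mixed model is fit by profiled REML written in-house (a random-intercept
model reduces to a one-dimensional optimization), which keeps the 500-replicate
simulation studies fast and bit-reproducible; it is validated against
statsmodels `MixedLM` and a naive dense reference in the test suite.

## CLI

```bash
# 1. simulate a cohort (writes trials.csv, participants.csv, run.json)
sstkit simulate --config config.yaml --seed 1 --out out/

# 2. integration-method SSRT estimates
sstkit estimate --trials out/trials.csv --out out/estimates.csv

# 3. exclusion rules (qc_report.csv, qc_summary.json, cleaned tables)
sstkit qc --estimates out/estimates.csv --participants out/participants.csv --out out/qc/

# 4. mixed models + BMI–SSRT correlation (analysis_report.{json,txt})
sstkit analyze --estimates out/estimates.csv --participants out/participants.csv --out out/

# a-priori power: minimal n per group for a one-sided correlation test
sstkit power 0.35 0.05 0.8 one          # -> 49 (exact method)
sstkit power 0.35 0.05 0.8 one --method fisher_z   # -> 50

# everything at once
sstkit run --config config.yaml --seed 1 --out out/
```

### Configuration

YAML mirroring the config dataclasses (`sstkit.config`); all keys optional,
shown with defaults:

```yaml
design:
  n_trials: 256          # 64 stop trials at p_stop 0.25
  p_stop: 0.25
  ssd_start_ms: 200.0
  ssd_step_ms: 50.0
  ssd_floor_ms: 50.0
  ssd_ceiling_ms: 900.0
cohort:
  groups:
    gamified:     {n: 50, go_shift_ms: 196.0, ssrt_shift_ms: 86.0,
                   age_mean_years: 29.6, age_sd_years: 11.3}
    nongamified:  {n: 50, age_mean_years: 25.3, age_sd_years: 7.2}
  overweight_fraction: 0.30
  go_mu_ms: 426.0        # + go_tau_ms = 583 ms mean go finishing time
  go_tau_ms: 157.0
  ssrt_mean_ms: 289.0
  overweight_go_shift_ms: 80.0
  overweight_ssrt_shift_ms: 35.0
  age_ssrt_slope_ms_per_year: 1.5
qc:
  pstop_low: 0.25
  pstop_high: 0.75
  height_min_cm: 147.0
  height_max_cm: 200.0
analysis:
  outlier_mad_threshold: 3.0
seed: 0
```

With the defaults, simulated group means land near go RT 607 vs 803 ms and
SSRT 297 vs 383 ms (nongamified vs gamified), with ~30% overweight members
per group. `CohortConfig.null(n_per_group=...)` switches every systematic
effect off for calibration studies.

## Trial-log schema

One row per trial:
`participant_id,group,trial_index,trial_type,stimulus_category,stimulus_id,ssd_ms,responded,rt_ms,correct`
— `ssd_ms` empty on go trials, `rt_ms` empty for omissions and successful
stops, `responded`/`correct` coded 0/1.

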