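# voctraj

Reusable analysis pipeline for describing how routine biomarkers and vital
signs evolve during non-complicated vaso-occlusive crisis (VOC) hospital
stays, from warehouse-style long-format records:

- **`voctraj.synthetic`** — seedable generator of patients, stays and
  irregularly sampled longitudinal measurements with known ground-truth mean
  trajectories, between-stay random effects, day/night cycles and planted
  "complicated-stay" contaminants for every exclusion rule.
- **`voctraj.cohort`** — the ordered inclusion/exclusion cascade (diagnosis
  code inclusion; patient-level opioid-use-disorder exclusion by code prefix
  or drug; ICU / coded severity 3–4 / transfusion / complication-code
  exclusions; 90th-percentile duration rule computed on the survivors), with
  a flowchart-style per-step report.
- **`voctraj.trajectory`** — the core method: a penalized B-spline (P-spline)
  mean curve fitted to all pooled points on the time-since-admission axis,
  smoothing weight chosen by cross-validation over stays, and a pointwise
  95% band from a cluster bootstrap that resamples whole stays. The grid is
  truncated wherever fewer than `min_support` stays still contribute.
- **`voctraj.thresholds`** — above/under-threshold proportion analysis over
  time windows (e.g. CRP ≥ 100 mg/L in the first 24 h; CRP below the normal
  limit after 48 h; temperature ≥ 38 °C at any point of the stay), with
  exact binomial confidence intervals.
- **`voctraj.stats`** — from-scratch two-sided Fisher exact test
  (probability-mass rule, log-space), Pearson chi-squared test, and Wilcoxon
  rank-sum test (exact enumeration for small samples, tie-corrected normal
  approximation otherwise), plus the table-one builder with per-genotype
  comparisons.
- **`voctraj.pipeline` / `voctraj.cli`** — CSV schemas, YAML configuration,
  figure export and a manifest-writing end-to-end runner.

## CLI

```bash
# generate a synthetic cohort (three CSV tables + truth log)
voctraj simulate --outdir data --seed 1

# apply the exclusion cascade and print the flowchart report
voctraj select --indir data --outdir out

# averaged trajectory with 95% band for one variable (CSV + figure)
voctraj trajectory --indir data --variable hemoglobin --outdir out --seed 1

# the three standard threshold-proportion queries
voctraj thresholds --indir data --outdir out

# baseline characteristics table with genotype comparisons
voctraj table1 --indir data --outdir out

# everything at once, simulating first, with a checksum manifest
voctraj run-all --simulate --outdir out --seed 1
```

All subcommands accept `--config config.yaml` to override simulation
truths, filter code sets, and spline/bootstrap settings (see
`voctraj.config` for the accepted keys).

### Input schemas (long format, CSV)

- `patients.csv`: `patient_id, sex, genotype, age_at_first_admission,
  steady_state_hb`, one boolean column per comorbidity flag.
- `stays.csv`: `stay_id, patient_id, admission, discharge` (ISO-8601),
  `icu_flag, severity_level, transfusion_flag, icd_codes, drugs`
  (semicolon-separated lists).
- `measurements.csv`: `stay_id, variable, time_hours` (or an absolute
  `timestamp`), `value, unit`.

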