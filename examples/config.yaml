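# Example configuration consumed by `voctraj simulate|select|trajectory|run-all --config`.
n_patients: 150
oud_rate: 0.03
contamination_rates:
  missing_inclusion_code: 0.04
  icu: 0.04
  severity: 0.04
  transfusion: 0.04
  complication: 0.04
intensity:
  early_per_day: 6.0
  late_per_day: 2.0
  early_window_hours: 48.0
truths:
  - variable: hemoglobin
    unit: g/dL
    points: [[0.0, 9.5], [120.0, 8.5], [240.0, 8.5]]
    between_stay_sd: 1.4
    residual_sd: 0.3
  - variable: crp
    unit: mg/L
    points: [[0.0, 15.0], [48.0, 60.0], [96.0, 60.0], [240.0, 40.0]]
    between_stay_sd: 20.0
    residual_sd: 8.0
  - variable: temperature
    unit: degC
    points: [[0.0, 37.0], [240.0, 37.0]]
    circadian_amplitude: 0.25
    between_stay_sd: 0.2
    residual_sd: 0.15
filters:
  inclusion_code: D57.0
  oud_code_prefix: F11
  oud_drugs: [methadone, buprenorphine]
  complication_codes: [A41.9, I26.0, J18.9]
  duration_percentile: 0.90
trajectories:
  grid_step: 6.0
  max_time: 240.0
  knot_spacing: 12.0
  n_bootstrap: 500
  ci_level: 0.95
  min_support: 10
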