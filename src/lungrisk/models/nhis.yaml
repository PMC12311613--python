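schema_version: 1
name: NHIS
population: ever_only
horizon: 6.6
form: cox_baseline
surrogate: true
source: >
  Korean National Health Insurance Service lung cancer risk model
  (ever smokers, 6.6-year horizon). Surrogate: published predictor set
  with re-derived log-hazard coefficients and baseline survival.
intercept: 0.0
terms:
  - field: age
    coef: 0.055
    transform: {type: center, value: 64}
  - field: sex
    coef: 1.0
    transform:
      type: categorical
      mapping: {male: 0.0, female: -0.15}
  - field: bmi
    coef: 1.0
    transform:
      type: bin
      breaks: [18.5, 24]
      values: [0.30, 0.10, 0.0]
  - field: alcohol_days_per_week
    coef: 0.020
    transform: {type: center, value: 2}
  - field: physical_activity_sessions_per_week
    coef: -0.030
    transform: {type: center, value: 3}
  - field: emphysema
    coef: 0.35
    transform: {type: indicator}
  - field: interstitial_lung_disease
    coef: 0.30
    transform: {type: indicator}
  - field: copd
    coef: 0.40
    transform: {type: indicator}
  - field: pack_years
    coef: 0.45
    transform: {type: log, offset: 1, center: 3.1}
  - field: smoking_status
    coef: 1.0
    transform:
      type: categorical
      mapping: {former: 0.0, current: 0.40}
baselines:
  s0: 0.986
  lp_center: 0.3
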