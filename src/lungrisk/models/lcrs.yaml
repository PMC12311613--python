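schema_version: 1
name: LCRS
population: all
horizon: 6
form: cox_baseline
surrogate: true
source: >
  Lung Cancer Risk Score developed in a Guangzhou cohort (all smoking
  groups, 6-year horizon). Surrogate: published predictor/group structure
  with re-derived log-hazard contributions and baseline survival.
intercept: 0.0
terms:
  - field: age
    coef: 1.0
    transform:
      type: bin
      breaks: [50, 55, 60, 65, 70, 75]
      values: [0.0, 0.25, 0.50, 0.75, 1.00, 1.25, 1.50]
  - field: bmi
    coef: 1.0
    transform:
      type: bin
      breaks: [18.5, 24]
      values: [0.20, 0.0, -0.10]
  - field: height
    coef: 1.0
    transform:
      type: bin
      breaks: [150, 155, 160]
      values: [0.0, 0.05, 0.10, 0.15]
  - field: education_level
    coef: 1.0
    transform:
      type: categorical
      mapping: {middle_school_or_below: 0.15, high_school: 0.05, college_or_above: 0.0}
  - field: physical_activity_minutes_per_week
    coef: 1.0
    transform:
      type: bin
      breaks: [30]
      values: [0.10, 0.0]
  - field: physical_activity_sessions_per_week
    coef: 1.0
    transform:
      type: bin
      breaks: [3]
      values: [0.10, 0.0]
  - field: family_history_lc
    coef: 1.0
    transform:
      type: categorical
      mapping: {none: 0.0, first_degree: 0.50}
  - field: prior_cancer
    coef: 0.30
    transform: {type: indicator}
  - field: chronic_bronchitis
    coef: 0.25
    transform: {type: indicator}
  - field: emphysema
    coef: 0.30
    transform: {type: indicator}
  - field: copd
    coef: 0.35
    transform: {type: indicator}
  - field: cough
    coef: 0.30
    transform: {type: indicator}
  - field: inhale_to_lungs
    coef: 0.15
    transform: {type: indicator}
    never_raw: 0
  - field: smoking_years
    coef: 1.0
    transform:
      type: bin
      breaks: [1, 10, 20, 30, 40, 50]
      values: [0.0, 0.10, 0.30, 0.60, 0.90, 1.20, 1.40]
    never_raw: 0
  - field: smoking_status
    coef: 1.0
    transform:
      type: categorical
      mapping: {never: 0.0, former: 0.10, current: 0.35}
  - field: cigarettes_per_day
    coef: 1.0
    transform:
      type: bin
      breaks: [1, 10, 15, 20, 25, 30, 35]
      values: [0.0, 0.05, 0.10, 0.15, 0.20, 0.22, 0.25, 0.30]
    never_raw: 0
baselines:
  s0: 0.995
  lp_center: 1.2
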