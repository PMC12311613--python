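schema_version: 1
name: OWL
population: all
horizon: 6
form: logistic_direct
surrogate: true
source: >
  Pan Z et al. Optimized early warning model for lung cancer risk (OWL).
  The original calculator is a gradient-boosted (XGBoost) ensemble whose
  trained weights are not publicly reprinted; this spec is a documented
  logistic surrogate built from the publication's predictor set and
  reported effect directions. Flagged surrogate to keep provenance honest.
intercept: -6.0
terms:
  - field: age
    coef: 0.070
    transform: {type: center, value: 62}
  - field: sex
    coef: 1.0
    transform:
      type: categorical
      mapping: {male: 0.25, female: 0.0}
  - field: education_level
    coef: -0.060
    transform:
      type: categorical
      mapping: {middle_school_or_below: 2, high_school: 3, college_or_above: 5}
      center: 4
  - field: bmi
    coef: -0.030
    transform: {type: center, value: 23.8}
  - field: family_history_lc
    coef: 1.0
    transform:
      type: categorical
      mapping: {none: 0.0, first_degree: 0.55}
  - field: chronic_bronchitis
    coef: 0.25
    transform: {type: indicator}
  - field: emphysema
    coef: 0.30
    transform: {type: indicator}
  - field: copd
    coef: 0.35
    transform: {type: indicator}
  - field: diabetes
    coef: 0.10
    transform: {type: indicator}
  - field: age_started
    coef: -0.010
    transform: {type: center, value: 22}
    never_raw: 22
  - field: pack_years
    coef: 0.28
    transform: {type: log, offset: 1}
    never_raw: 0
  - field: smoking_years
    coef: 0.15
    transform: {type: log, offset: 1}
    never_raw: 0
  - field: smoking_status
    coef: 1.0
    transform:
      type: categorical
      mapping: {never: 0.0, former: 0.20, current: 0.45}
  - field: quit_years
    coef: -0.020
    transform: {type: identity}
    never_raw: 0
  - field: cigarettes_per_day
    coef: 0.10
    transform: {type: log, offset: 1}
    never_raw: 0
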