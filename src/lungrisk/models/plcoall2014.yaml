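schema_version: 1
name: PLCOall2014
population: all
horizon: 6
form: logistic_direct
surrogate: true
source: >
  Tammemagi MC et al. Evaluation of the lung cancer risks at which to
  screen ever- and never-smokers. PLoS Med 2014;11:e1001764
  (all-participant extension of the PLCO 6-year model). Coefficients here
  are a documented surrogate re-derived from the reported effect
  directions and magnitudes, not an exact transcription.
intercept: -5.85
terms:
  - field: age
    coef: 0.078
    transform: {type: center, value: 62}
  - field: education_level
    coef: -0.081
    transform:
      type: categorical
      mapping: {middle_school_or_below: 2, high_school: 3, college_or_above: 5}
      center: 4
  - field: bmi
    coef: -0.027
    transform: {type: center, value: 27}
  - field: copd
    coef: 0.36
    transform: {type: indicator}
  - field: prior_cancer
    coef: 0.46
    transform: {type: indicator}
  - field: family_history_lc
    coef: 0.59
    transform:
      type: categorical
      mapping: {none: 0, first_degree: 1}
  - field: smoking_status
    coef: 1.0
    transform:
      type: categorical
      mapping: {never: 0.0, former: 0.46, current: 0.72}
  - field: smoking_years
    coef: 0.028
    transform: {type: center, value: 27}
    never_raw: 27
  - field: quit_years
    coef: -0.029
    transform: {type: center, value: 10}
    never_raw: 10
  - field: cigarettes_per_day
    coef: 0.25
    transform: {type: log, offset: 1, center: 2.8904}
    never_raw: 17
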