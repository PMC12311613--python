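schema_version: 1
name: PLCOm2012
population: ever_only
horizon: 6
form: logistic_direct
surrogate: false
source: >
  Tammemagi MC et al. Selection criteria for lung-cancer screening.
  N Engl J Med 2013;368:728-736 (6-year lung cancer incidence model,
  ever smokers). Race/ethnicity term omitted: no such predictor is
  collected here, reference level assumed (contribution 0). Education is
  mapped from three local levels onto the model's 6-point ordinal scale
  (middle school or below -> 2, high school -> 3, college or above -> 5).
intercept: -4.532506
terms:
  - field: age
    coef: 0.0778868
    transform: {type: center, value: 62}
  - field: education_level
    coef: -0.0812744
    transform:
      type: categorical
      mapping: {middle_school_or_below: 2, high_school: 3, college_or_above: 5}
      center: 4
  - field: bmi
    coef: -0.0274194
    transform: {type: center, value: 27}
  - field: copd
    coef: 0.3553063
    transform: {type: indicator}
  - field: prior_cancer
    coef: 0.4589971
    transform: {type: indicator}
  - field: family_history_lc
    coef: 0.587185
    transform:
      type: categorical
      mapping: {none: 0, first_degree: 1}
  - field: smoking_status
    coef: 0.2597431
    transform:
      type: categorical
      mapping: {former: 0, current: 1}
  - field: cigarettes_per_day
    coef: -1.822606
    transform: {type: power, scale: 10, exponent: -1, center: 0.4021541613}
    truncate: [1, null]
  - field: smoking_years
    coef: 0.0317321
    transform: {type: center, value: 27}
  - field: quit_years
    coef: -0.0308572
    transform: {type: center, value: 10}
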