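schema_version: 1
name: LCRAT
population: ever_only
horizon: 5
form: annual_recursion
surrogate: true
source: >
  Katki HA et al. Development and validation of risk models to select
  ever-smokers for CT lung cancer screening (LCRAT). JAMA
  2016;315:2300-2311 (annual absolute-risk recursion with competing
  mortality). Surrogate: piecewise-constant age/sex hazard tables and
  re-derived relative-hazard coefficients for the published predictor set.
intercept: 0.0
terms:
  - field: education_level
    coef: -0.090
    transform:
      type: categorical
      mapping: {middle_school_or_below: 2, high_school: 3, college_or_above: 5}
      center: 4
  - field: bmi
    coef: -0.025
    transform: {type: center, value: 27}
  - field: emphysema
    coef: 0.50
    transform: {type: indicator}
  - field: family_history_lc
    coef: 1.0
    transform:
      type: categorical
      mapping: {none: 0.0, first_degree: 0.45}
  - field: smoking_years
    coef: 0.030
    transform: {type: center, value: 27}
  - field: quit_years
    coef: -0.030
    transform: {type: center, value: 5}
  - field: pack_years
    coef: 0.30
    transform: {type: log, offset: 1, center: 3.1}
  - field: cigarettes_per_day
    coef: -1.50
    transform: {type: power, scale: 10, exponent: -1, center: 0.40}
    truncate: [1, null]
baselines:
  lp_center: 0.0
  annual_lc_hazard:
    age_breaks: [50, 55, 60, 65, 70, 75, 80, 85]
    male:   [0.0003, 0.0006, 0.0010, 0.0015, 0.0021, 0.0028, 0.0034, 0.0038, 0.0040]
    female: [0.0002, 0.0004, 0.0007, 0.0010, 0.0014, 0.0019, 0.0023, 0.0026, 0.0028]
  annual_mort_hazard:
    age_breaks: [50, 55, 60, 65, 70, 75, 80, 85]
    male:   [0.004, 0.006, 0.009, 0.014, 0.022, 0.035, 0.055, 0.085, 0.130]
    female: [0.0028, 0.0042, 0.0063, 0.0098, 0.0154, 0.0245, 0.0385, 0.0595, 0.0910]
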