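schema_version: 1
name: LLPi
population: all
horizon: 8.7
form: cox_baseline
surrogate: true
source: >
  Marcus MW et al. LLPi: Liverpool Lung Project risk prediction model for
  lung cancer incidence. Cancer Prev Res 2015;8:570-575 (all participants,
  8.7-year horizon). Surrogate: published predictor set with re-derived
  log-hazard coefficients and baseline survival.
intercept: 0.0
terms:
  - field: age
    coef: 0.070
    transform: {type: center, value: 62}
  - field: sex
    coef: 1.0
    transform:
      type: categorical
      mapping: {male: 0.30, female: 0.0}
  - field: family_history_lc
    coef: 1.0
    transform:
      type: categorical
      mapping: {none: 0.0, first_degree: 0.55}
  - field: prior_cancer
    coef: 0.45
    transform: {type: indicator}
  - field: copd
    coef: 0.40
    transform: {type: indicator}
  - field: smoking_years
    coef: 0.25
    transform: {type: log, offset: 1}
    never_raw: 0
baselines:
  s0: 0.990
  lp_center: 0.5
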