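schema_version: 1
name: HUNT
population: ever_only
horizon: 6
form: cox_baseline
surrogate: true
source: >
  Markaki M et al. A validated clinical risk prediction model for lung
  cancer in smokers of all ages and exposure types (HUNT Lung Cancer
  Model). EBioMedicine 2018;31:36-46. Surrogate: published predictor set
  with re-derived log-hazard coefficients and a 6-year baseline survival.
intercept: 0.0
terms:
  - field: age
    coef: 0.060
    transform: {type: center, value: 64}
  - field: sex
    coef: 1.0
    transform:
      type: categorical
      mapping: {male: 0.0, female: -0.10}
  - field: bmi
    coef: -0.020
    transform: {type: center, value: 23}
  - field: cough
    coef: 0.40
    transform: {type: indicator}
  - field: secondhand_smoke_hours_per_day
    coef: 0.020
    transform: {type: identity}
  - field: pack_years
    coef: 0.50
    transform: {type: log, offset: 1, center: 3.1}
  - field: quit_years
    coef: -0.025
    transform: {type: center, value: 5}
  - field: cigarettes_per_day
    coef: 0.010
    transform: {type: center, value: 16}
baselines:
  s0: 0.988
  lp_center: 0.0
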