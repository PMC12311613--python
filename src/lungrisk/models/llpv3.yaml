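schema_version: 1
name: LLPv3
population: all
horizon: 5
form: rr_times_incidence
surrogate: true
source: >
  Field JK et al. Liverpool Lung Project lung cancer risk stratification
  model version 3 (recalibrated age weighting; lower baseline absolute
  risks than version 2). Surrogate transcription: same risk-factor odds
  ratios as the version 2 spec with a down-weighted baseline table.
intercept: 0.0
terms:
  - field: smoking_years
    coef: 1.0
    transform:
      type: bin
      breaks: [1, 21, 41]
      values: [0.0, 0.7701, 1.4516, 2.0807]
    never_raw: 0
  - field: family_history_lc
    coef: 1.0
    transform:
      type: categorical
      mapping: {none: 0.0, first_degree: 0.599}
  - field: asbestos_exposure
    coef: 0.6366
    transform: {type: indicator}
  - field: prior_cancer
    coef: 0.6729
    transform: {type: indicator}
  - field: copd
    coef: 0.4383
    transform: {type: indicator}
baselines:
  baseline_risk:
    age_breaks: [50, 55, 60, 65, 70, 75, 80]
    male:   [0.0006, 0.0010, 0.0016, 0.0024, 0.0034, 0.0045, 0.0055, 0.0065]
    female: [0.0003, 0.0005, 0.0008, 0.0012, 0.0017, 0.0023, 0.0028, 0.0033]
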