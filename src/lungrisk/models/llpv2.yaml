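schema_version: 1
name: LLPv2
population: all
horizon: 5
form: rr_times_incidence
surrogate: true
source: >
  Cassidy A et al. The LLP risk model: an individual risk prediction model
  for lung cancer. Br J Cancer 2008;98:270-276 (case-control odds ratios
  combined with age/sex baseline 5-year absolute risk). Odds ratios and
  the baseline table are a documented surrogate of the published values;
  the published pneumonia term is operationalised with the COPD field
  (the closest collected predictor).
intercept: 0.0
terms:
  - field: smoking_years
    coef: 1.0
    transform:
      type: bin
      breaks: [1, 21, 41]
      values: [0.0, 0.7701, 1.4516, 2.0807]   # log ORs: 1 / 2.16 / 4.27 / 8.01
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
    male:   [0.0008, 0.0015, 0.0025, 0.0040, 0.0060, 0.0080, 0.0100, 0.0120]
    female: [0.0004, 0.0008, 0.0012, 0.0020, 0.0030, 0.0040, 0.0050, 0.0060]
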