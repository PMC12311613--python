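schema_version: 1
name: Pittsburgh
population: ever_only
horizon: 6
form: logistic_direct
surrogate: true
source: >
  Wilson DO, Weissfeld J. A simple model for predicting lung cancer
  occurrence in a lung cancer screening program (Pittsburgh Predictor).
  Lung Cancer 2015;89:31-37. Surrogate: the published predictor set and
  ordinal group structure with re-derived log-odds contributions.
intercept: -6.6
terms:
  - field: age
    coef: 1.0
    transform:
      type: bin
      breaks: [50, 55, 60, 65, 70, 75]
      values: [0.0, 0.3, 0.6, 0.9, 1.2, 1.5, 1.8]
  - field: smoking_years
    coef: 1.0
    transform:
      type: bin
      breaks: [10, 20, 30, 40, 50]
      values: [0.0, 0.3, 0.7, 1.1, 1.5, 1.8]
  - field: smoking_status
    coef: 1.0
    transform:
      type: categorical
      mapping: {former: 0.0, current: 0.5}
  - field: cigarettes_per_day
    coef: 1.0
    transform:
      type: bin
      breaks: [10, 15, 20, 25, 30, 35]
      values: [0.0, 0.15, 0.25, 0.35, 0.40, 0.45, 0.50]
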