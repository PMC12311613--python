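schema_version: 1
name: Bach
population: ever_only
horizon: 10
form: annual_recursion
surrogate: true
source: >
  Bach PB et al. Variations in lung cancer risk among smokers.
  J Natl Cancer Inst 2003;95:470-478 (annual lung-cancer and
  competing-mortality hazards, 10-year absolute risk by recursion).
  Surrogate: the published smooth hazard functions are represented by
  piecewise-constant age/sex tables and re-derived relative-hazard terms.
intercept: 0.0
terms:
  - field: smoking_years
    coef: 1.0
    transform:
      type: bin
      breaks: [1, 10, 20, 30, 40, 50]
      values: [0.0, 0.10, 0.40, 0.80, 1.20, 1.50, 1.70]
  - field: smoking_status
    coef: 1.0
    transform:
      type: categorical
      mapping: {former: 0.0, current: 0.35}
  - field: cigarettes_per_day
    coef: 1.0
    transform:
      type: bin
      breaks: [10, 20, 30]
      values: [0.0, 0.20, 0.40, 0.50]
  - field: asbestos_exposure
    coef: 0.20
    transform: {type: indicator}
baselines:
  lp_center: 1.0
  annual_lc_hazard:
    age_breaks: [50, 55, 60, 65, 70, 75, 80, 85]
    male:   [0.0002, 0.0004, 0.0007, 0.0011, 0.0016, 0.0022, 0.0028, 0.0032, 0.0035]
    female: [0.00012, 0.00024, 0.00042, 0.00066, 0.00096, 0.0013, 0.0017, 0.0019, 0.0021]
  annual_mort_hazard:
    age_breaks: [50, 55, 60, 65, 70, 75, 80, 85]
    male:   [0.004, 0.006, 0.009, 0.014, 0.022, 0.035, 0.055, 0.085, 0.130]
    female: [0.0028, 0.0042, 0.0063, 0.0098, 0.0154, 0.0245, 0.0385, 0.0595, 0.0910]
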