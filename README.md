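# lungrisk

A toolkit for externally validating epidemiological lung cancer risk
prediction calculators and comparing them with screening eligibility
criteria, exercised on synthetic cohorts with a known, exactly
reproducible structure.

## What it does

- **Cohort model** (`lungrisk.cohort`) — typed subject/follow-up records,
  CSV round-trip I/O (empty cell = missing, `—` = not applicable), hard
  invariant validation with row-level diagnostics, smoking-group subsetting.
- **Synthetic cohorts** (`lungrisk.synthetic`) — generates a 30,404-subject
  cohort whose stratified categorical marginals (smoking group × case
  status), cumulative event schedule, and MCAR missingness block (382
  subjects) are reproduced *exactly by construction*; also a
  ground-truth mode that simulates outcomes from a known risk model.
- **Model registry** (`lungrisk.registry`) — 12 risk calculators (LCRAT,
  LLPv2/v3, Pittsburgh, HUNT, OWL, LCRS, PLCOm2012, PLCOall2014, NHIS,
  LLPi, Bach) shipped as declarative YAML specs. Coefficients are
  transcribed where the original publication prints them (PLCOm2012) and
  otherwise flagged `surrogate: true` with the published predictor set,
  form, horizon and population (see each spec's `source` note).
- **Risk engines** (`lungrisk.engines`) — four absolute-risk forms:
  direct logistic, Cox baseline survival, relative-risk × baseline
  incidence (odds scale), and an annual recursion with competing
  mortality (fractional final year pro-rated).
- **Screening criteria** (`lungrisk.criteria`) — T/CPMA 013-2020,
  USPSTF-2021 and NELSON eligibility with printed boundary inclusivity;
  unoperationalizable clauses use explicit configurable proxies.
- **Validation statistics** (`lungrisk.validation`) — Mann–Whitney AUC
  with DeLong intervals, expected/observed (E/O) ratio with Poisson
  intervals, quartile calibration groups, MICE (PMM + multinomial
  sampling) and Rubin's-rules pooling, high-risk-group feature tables.
- **Screening comparison** (`lungrisk.comparison`) — count-matched
  thresholds (exact tie resolution), sensitivity/specificity and cases
  captured per horizon.
- **Pipeline & CLI** (`lungrisk.pipeline`, `lungrisk.cli`) — deterministic
  end-to-end runs producing JSON/CSV report bundles.

## CLI

```bash
lungrisk simulate --seed 1 --out cohort.csv        # synthetic cohort
lungrisk models list                               # bundled model specs
lungrisk score --model PLCOm2012 --cohort cohort.csv --out preds.csv
lungrisk criteria --name tcpma --cohort cohort.csv --out elig.csv
lungrisk validate --cohort cohort.csv --model LLPi --stratum ever \
                  --m 5 --seed 1 --out report.json
lungrisk compare --cohort cohort.csv --criteria uspstf --out comparison.csv
lungrisk report --seed 1 --outdir out/             # full pipeline
```

Exit codes: 0 success, 2 configuration/spec error, 1 data error.

## Notes on scope

The source cohort data are not public, so published real-data AUC / E/O
values are not reproducible here; the test suite instead verifies the
printed cohort structure by construction plus property-based oracles
(brute-force AUC concordance, outcome-tree enumeration for the annual
recursion, self-calibration of simulated outcomes, exact count matching,
criteria truth tables, Rubin pooling arithmetic, MICE mean recovery).
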