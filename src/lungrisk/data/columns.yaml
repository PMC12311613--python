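# Default column dictionary (version 1): external CSV header -> canonical
# field name.  Adapt a copy of this file to ingest cohorts with different
# headers (pass it to read_cohort via column_map / load_column_map).
schema_version: 1
columns:
  id: id
  sex: sex
  age: age
  height: height
  bmi: bmi
  education_level: education_level
  smoking_status: smoking_status
  age_started: age_started
  smoking_years: smoking_years
  quit_years: quit_years
  cigarettes_per_day: cigarettes_per_day
  pack_years: pack_years
  inhale_to_lungs: inhale_to_lungs
  secondhand_smoke_hours_per_day: secondhand_smoke_hours_per_day
  alcohol_days_per_week: alcohol_days_per_week
  physical_activity_minutes_per_week: physical_activity_minutes_per_week
  physical_activity_sessions_per_week: physical_activity_sessions_per_week
  family_history_lc: family_history_lc
  asbestos_exposure: asbestos_exposure
  prior_cancer: prior_cancer
  copd: copd
  chronic_bronchitis: chronic_bronchitis
  emphysema: emphysema
  interstitial_lung_disease: interstitial_lung_disease
  diabetes: diabetes
  cough: cough
  event: event
  time: time
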