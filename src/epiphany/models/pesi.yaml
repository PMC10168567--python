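# PESI (Pulmonary Embolism Severity Index), transcribed from its original
# publication (Aujesky et al., Am J Respir Crit Care Med 2005).  Age enters as
# its value in years.  Several items (heart failure, chronic lung disease,
# temperature, altered mental status) are not part of the cohort schema and
# are read from optional extra columns; with the shipped `missing: error`
# policy the score is unevaluable without them, and the pipeline will skip it
# with a named warning rather than guess.  Predicted 30-day mortality per
# class uses the midpoint of the range reported in the original validation.
name: pesi
enabled: true
items:
  - {name: age_years, feature: age, op: points_from_value}
  - {name: male_sex, feature: sex, op: eq, value: male, points: 10}
  - {name: cancer, op: always, points: 30}
  - {name: heart_failure, feature: heart_failure, op: eq, value: true, points: 10,
     missing: error}
  - {name: chronic_lung_disease, feature: chronic_lung_disease, op: eq, value: true,
     points: 10, missing: error}
  - {name: hr_ge_110, feature: hr, op: ge, value: 110, points: 20}
  - {name: sbp_lt_100, feature: sbp, op: lt, value: 100, points: 30}
  - {name: rr_ge_30, feature: rr, op: ge, value: 30, points: 20}
  - {name: temp_lt_36, feature: temperature, op: lt, value: 36, points: 20,
     missing: error}
  - {name: altered_mental_status, feature: altered_mental_status, op: eq,
     value: true, points: 60, missing: error}
  - {name: spo2_lt_90, feature: spo2, op: lt, value: 90, points: 20}
classes:
  - {name: class_i, max: 65, predicted_30d_mortality: 0.008}
  - {name: class_ii, min: 66, max: 85, predicted_30d_mortality: 0.026}
  - {name: class_iii, min: 86, max: 105, predicted_30d_mortality: 0.052}
  - {name: class_iv, min: 106, max: 125, predicted_30d_mortality: 0.077}
  - {name: class_v, min: 126, predicted_30d_mortality: 0.173}
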