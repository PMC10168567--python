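# Simplified PESI (sPESI), transcribed from its original publication
# (Jimenez et al., Arch Intern Med 2010).  One point per item; 0 points =
# low risk, >=1 = high risk.  In a cohort restricted to active cancer the
# cancer item is always satisfied, so no episode can be sPESI low-risk.
# Predicted 30-day mortality per class follows the original report.
# The chronic cardiopulmonary-disease item is not part of the cohort schema;
# it is read from the optional extra column `chronic_cardiopulmonary` and,
# by the shipped policy, assumed absent when the column is missing.
name: spesi
enabled: true
items:
  - {name: age_gt_80, feature: age, op: gt, value: 80, points: 1}
  - {name: cancer, op: always, points: 1}
  - {name: chronic_cardiopulmonary_disease, feature: chronic_cardiopulmonary,
     op: eq, value: true, points: 1, missing: assume_false}
  - {name: hr_ge_110, feature: hr, op: ge, value: 110, points: 1}
  - {name: sbp_lt_100, feature: sbp, op: lt, value: 100, points: 1}
  - {name: spo2_lt_90, feature: spo2, op: lt, value: 90, points: 1}
classes:
  - {name: low, min: 0, max: 0, predicted_30d_mortality: 0.010}
  - {name: high, min: 1, max: 6, predicted_30d_mortality: 0.109}
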