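# Adapted Hestia criteria for the oncological population.
# An episode is Hestia-positive when at least one criterion is met; all
# inequalities are applied exactly as printed (boundary values do not trigger).
# The bleeding items ("clinically relevant bleeding", "high risk of bleeding")
# are clinical-judgment flags supplied in the input, not computed.
name: hestia-adapted
criteria:
  - {name: sbp_lt_100, feature: sbp, op: lt, value: 100}
  - {name: spo2_lt_90, feature: spo2, op: lt, value: 90}
  - {name: rr_ge_30, feature: rr, op: ge, value: 30}
  - {name: hr_ge_110, feature: hr, op: ge, value: 110}
  - {name: dyspnea, feature: pe_symptoms, op: contains, value: sudden_or_progressive_dyspnea}
  - {name: other_admission_criterion, feature: other_admission_criterion, op: eq, value: true}
  - {name: clinically_relevant_bleeding, feature: clinically_relevant_bleeding, op: eq, value: true}
  - {name: high_bleeding_risk, feature: high_bleeding_risk, op: eq, value: true}
  - {name: platelets_lt_50000, feature: platelets, op: lt, value: 50000}
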