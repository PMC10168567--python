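# Machine-readable schema of the episode-level cohort CSV.
# Booleans are written 0/1; sets are semicolon-joined tokens; missing optional
# values are empty strings.  Categorical values are case-insensitive on read
# and canonical lower-case on write.
name: cancer_pe_cohort
version: 1
columns:
  - {name: episode_id, type: string, required: true, unique: true}
  - {name: age, type: integer, required: true, min: 18}
  - {name: sex, type: categorical, required: true, values: [male, female]}
  - {name: ecog_ps, type: integer, required: true, min: 0, max: 4}
  - {name: tumor_type, type: string, required: true}
  - {name: stage_iv, type: boolean, required: true}
  - {name: recist, type: categorical, required: true, values: [cr, pr, sd, ned, pd, ne, uk]}
  - {name: primary_resected, type: boolean, required: true}
  - {name: sbp, type: number, required: true, min: 0, unit: mmHg}
  - {name: hr, type: number, required: true, min: 0, unit: beats/min}
  - {name: rr, type: number, required: true, min: 0, unit: breaths/min}
  - {name: spo2, type: number, required: true, min: 0, max: 100, unit: percent}
  - {name: pe_symptoms, type: set, required: true,
     values: [sudden_or_progressive_dyspnea, chest_pain, syncope]}
  - {name: presentation, type: categorical, required: true,
     values: [suspected, unsuspected_symptomatic, unsuspected_asymptomatic]}
  - {name: clinically_relevant_bleeding, type: boolean, required: true}
  - {name: high_bleeding_risk, type: boolean, required: true}
  - {name: platelets, type: number, required: true, min: 0, unit: per_mm3}
  - {name: other_admission_criterion, type: boolean, required: true}
  - {name: prior_anticoagulation, type: boolean, required: true}
  - {name: outpatient, type: boolean, required: true}
  - {name: complication_15d, type: boolean, required: true}
  - {name: complication_day, type: integer, required: false, min: 0, max: 15, unit: days}
  - {name: death_30d, type: boolean, required: true}
  - {name: os_time, type: number, required: false, min: 0, unit: months}
  - {name: os_event, type: boolean, required: false}
  - {name: bleed_time, type: number, required: false, min: 0, unit: months}
  - {name: bleed_status, type: categorical, required: false,
     values: [censored, bleeding, death_without_bleeding]}
  - {name: rethrombosis_time, type: number, required: false, min: 0, unit: months}
  - {name: rethrombosis_status, type: categorical, required: false,
     values: [censored, rethrombosis, death_without_rethrombosis]}
invariants:
  - unsuspected_asymptomatic presentation implies pe_symptoms empty
  - complication_15d implies complication_day in [0, 15] when present
  - death_30d implies os_event and os_time <= 30/30.44 months
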