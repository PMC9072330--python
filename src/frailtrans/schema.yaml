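version: 1
name: frailtrans-cohort
description: >
  One row per participant. Missing values are empty cells. Binary fields are
  0/1; the five frailty items appear twice (suffix _base at baseline, _fu at
  follow-up) as ternary 0/1/empty.
columns:
  - {name: id, type: string}
  - {name: gender, type: categorical, levels: [woman, man]}
  - {name: age, type: continuous, units: years}
  - {name: education, type: categorical, levels: [low, middle, high]}
  - {name: smoking, type: categorical, levels: [never, ever]}
  - {name: self_rated_health, type: categorical, levels: [excellent_good, moderate_to_very_poor]}
  - {name: living_alone, type: binary}
  - {name: bmi_cat, type: categorical, levels: [lt25, 25-29.9, ge30]}
  - {name: polypharmacy, type: binary}
  - {name: hospitalization_cat, type: categorical, levels: ['0', 1-2, ge3]}
  - {name: cognitive_impairment, type: binary}
  - {name: stroke, type: binary}
  - {name: chf, type: binary}
  - {name: diabetes, type: binary}
  - {name: cancer, type: binary}
  - {name: osteoarthritis, type: binary}
  - {name: copd, type: binary}
  - {name: egfr_lt60, type: binary}
  - {name: acr_ge30, type: binary}
  - {name: shrinking_base, type: binary}
  - {name: exhaustion_base, type: binary}
  - {name: low_physical_activity_base, type: binary}
  - {name: slowness_base, type: binary}
  - {name: weakness_base, type: binary}
  - {name: shrinking_fu, type: binary}
  - {name: exhaustion_fu, type: binary}
  - {name: low_physical_activity_fu, type: binary}
  - {name: slowness_fu, type: binary}
  - {name: weakness_fu, type: binary}
  - {name: died_in_followup, type: binary}
  - {name: followup_time, type: continuous, units: years}
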