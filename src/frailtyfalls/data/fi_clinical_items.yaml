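# Default 40-item clinical frailty-index (deficit accumulation) schema.
#
# Items are organised by the standard deficit domains: symptoms and signs,
# body-mass index, comorbidities, functional ability, cognitive status, and
# sensory function. Item identities here are a generic admission-assessment
# schema; a site deploys its own item list by swapping this file. Each item
# is scored 0 (absent), 0.5 (partial), or 1 (full deficit); missing items
# are simply absent from the deficits table.
name: default-40
items:
  # symptoms and signs
  - {item_id: fatigue, domain: symptoms}
  - {item_id: appetite_loss, domain: symptoms}
  - {item_id: weight_loss, domain: symptoms}
  - {item_id: dizziness, domain: symptoms}
  - {item_id: dyspnea, domain: symptoms}
  - {item_id: edema, domain: symptoms}
  - {item_id: chronic_pain, domain: symptoms}
  - {item_id: sleep_disturbance, domain: symptoms}
  - {item_id: incontinence, domain: symptoms}
  - {item_id: pressure_ulcer, domain: symptoms}
  # body-mass index
  - {item_id: low_bmi, domain: bmi}
  - {item_id: high_bmi, domain: bmi}
  # comorbidities
  - {item_id: heart_disease, domain: comorbidity}
  - {item_id: lung_disease, domain: comorbidity}
  - {item_id: kidney_disease, domain: comorbidity}
  - {item_id: liver_disease, domain: comorbidity}
  - {item_id: diabetes, domain: comorbidity}
  - {item_id: cancer_history, domain: comorbidity}
  - {item_id: stroke_history, domain: comorbidity}
  - {item_id: hypertension, domain: comorbidity}
  # functional ability
  - {item_id: needs_help_feeding, domain: functional}
  - {item_id: needs_help_bathing, domain: functional}
  - {item_id: needs_help_grooming, domain: functional}
  - {item_id: needs_help_dressing, domain: functional}
  - {item_id: needs_help_toileting, domain: functional}
  - {item_id: needs_help_transfer, domain: functional}
  - {item_id: needs_help_stairs, domain: functional}
  - {item_id: needs_help_walking, domain: functional}
  - {item_id: uses_walking_aid, domain: functional}
  - {item_id: bedbound, domain: functional}
  # cognitive status
  - {item_id: disorientation, domain: cognitive}
  - {item_id: memory_impairment, domain: cognitive}
  - {item_id: delirium, domain: cognitive}
  - {item_id: depressive_signs, domain: cognitive}
  - {item_id: communication_difficulty, domain: cognitive}
  # sensory function
  - {item_id: vision_impairment, domain: sensory}
  - {item_id: hearing_impairment, domain: sensory}
  - {item_id: dysphagia, domain: sensory}
  - {item_id: dentition_problem, domain: sensory}
  - {item_id: grip_weakness, domain: sensory}
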