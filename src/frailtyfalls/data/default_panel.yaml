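# Default 35-analyte FI-lab reference panel.
#
# Admission blood panel: CBC, electrolytes, renal/liver/protein markers,
# lipids, inflammation and endocrine analytes with textbook adult reference
# intervals. Limits are inclusive: a value equal to a limit is normal.
# Sex-specific intervals override the shared limits where given.
# The panel is configuration, not code — swap the file to change the panel.
name: default-35
analytes:
  - {analyte_id: wbc, units: 10^9/L, lower_limit: 3.5, upper_limit: 9.5}
  - analyte_id: rbc
    units: 10^12/L
    sex_specific:
      male: {lower_limit: 4.3, upper_limit: 5.7}
      female: {lower_limit: 3.8, upper_limit: 5.1}
  - analyte_id: hemoglobin
    units: g/dL
    sex_specific:
      male: {lower_limit: 13.5, upper_limit: 17.5}
      female: {lower_limit: 12.0, upper_limit: 15.5}
  - analyte_id: hematocrit
    units: "%"
    sex_specific:
      male: {lower_limit: 40.0, upper_limit: 52.0}
      female: {lower_limit: 36.0, upper_limit: 48.0}
  - {analyte_id: mcv, units: fL, lower_limit: 80.0, upper_limit: 100.0}
  - {analyte_id: mchc, units: g/dL, lower_limit: 32.0, upper_limit: 36.0}
  - {analyte_id: platelets, units: 10^9/L, lower_limit: 150.0, upper_limit: 400.0}
  - {analyte_id: sodium, units: mmol/L, lower_limit: 135.0, upper_limit: 145.0}
  - {analyte_id: potassium, units: mmol/L, lower_limit: 3.5, upper_limit: 5.0}
  - {analyte_id: chloride, units: mmol/L, lower_limit: 98.0, upper_limit: 107.0}
  - {analyte_id: calcium, units: mg/dL, lower_limit: 8.5, upper_limit: 10.5}
  - {analyte_id: phosphate, units: mg/dL, lower_limit: 2.5, upper_limit: 4.5}
  - {analyte_id: magnesium, units: mg/dL, lower_limit: 1.7, upper_limit: 2.4}
  - {analyte_id: urea_nitrogen, units: mg/dL, lower_limit: 8.0, upper_limit: 20.0}
  - analyte_id: creatinine
    units: mg/dL
    sex_specific:
      male: {lower_limit: 0.7, upper_limit: 1.3}
      female: {lower_limit: 0.5, upper_limit: 1.1}
  - analyte_id: uric_acid
    units: mg/dL
    sex_specific:
      male: {lower_limit: 3.5, upper_limit: 7.2}
      female: {lower_limit: 2.6, upper_limit: 6.0}
  - {analyte_id: glucose, units: mg/dL, lower_limit: 70.0, upper_limit: 110.0}
  - {analyte_id: total_protein, units: g/dL, lower_limit: 6.3, upper_limit: 8.2}
  - {analyte_id: albumin, units: g/dL, lower_limit: 3.5, upper_limit: 5.0}
  - {analyte_id: total_bilirubin, units: mg/dL, lower_limit: 0.2, upper_limit: 1.2}
  - {analyte_id: ast, units: U/L, lower_limit: 8.0, upper_limit: 40.0}
  - {analyte_id: alt, units: U/L, lower_limit: 5.0, upper_limit: 45.0}
  - {analyte_id: alp, units: U/L, lower_limit: 40.0, upper_limit: 130.0}
  - analyte_id: ggt
    units: U/L
    sex_specific:
      male: {lower_limit: 10.0, upper_limit: 70.0}
      female: {lower_limit: 6.0, upper_limit: 45.0}
  - {analyte_id: ldh, units: U/L, lower_limit: 120.0, upper_limit: 250.0}
  - analyte_id: creatine_kinase
    units: U/L
    sex_specific:
      male: {lower_limit: 40.0, upper_limit: 200.0}
      female: {lower_limit: 30.0, upper_limit: 170.0}
  - {analyte_id: amylase, units: U/L, lower_limit: 30.0, upper_limit: 110.0}
  - {analyte_id: crp, units: mg/dL, lower_limit: null, upper_limit: 0.3}
  - {analyte_id: total_cholesterol, units: mg/dL, lower_limit: 130.0, upper_limit: 220.0}
  - {analyte_id: triglycerides, units: mg/dL, lower_limit: 35.0, upper_limit: 160.0}
  - analyte_id: hdl_cholesterol
    units: mg/dL
    sex_specific:
      male: {lower_limit: 35.0, upper_limit: 80.0}
      female: {lower_limit: 40.0, upper_limit: 90.0}
  - {analyte_id: ldl_cholesterol, units: mg/dL, lower_limit: 60.0, upper_limit: 140.0}
  - analyte_id: iron
    units: ug/dL
    sex_specific:
      male: {lower_limit: 60.0, upper_limit: 170.0}
      female: {lower_limit: 50.0, upper_limit: 150.0}
  - {analyte_id: tsh, units: mIU/L, lower_limit: 0.4, upper_limit: 4.0}
  - {analyte_id: hba1c, units: "%", lower_limit: 4.0, upper_limit: 6.0}
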