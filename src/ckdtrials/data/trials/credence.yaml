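# CREDENCE enrolment criteria as operationalized against primary-care data.
# Bounds carry explicit open/closed flags; laboratory thresholds are the
# mg/mmol and mmol/mol values used in the emulation (converted from the
# trial's mg/g and NGSP % criteria).
name: CREDENCE
inclusion:
  - id: age_min_30
    description: ">=30 years of age"
    kind: min_age
    params: {min: 30}
    reason_fail: age
  - id: t2d
    description: "Type 2 diabetes (ontological: codes, HbA1c, prescriptions)"
    kind: t2d
    params: {}
    reason_fail: no_t2d
  - id: hba1c_range
    description: "HbA1c >=47.5 and <=107.7 mmol/mol"
    kind: lab_range
    params: {concept: hba1c, lo: 47.5, hi: 107.7, lo_incl: true, hi_incl: true}
    reason_fail: hba1c
    reason_missing: hba1c
  - id: egfr_range
    description: "eGFR >=30 and <90 mL/min/1.73 m2 (CKD-EPI 2021)"
    kind: lab_range
    params: {concept: egfr, lo: 30, hi: 90, lo_incl: true, hi_incl: false}
    reason_fail: egfr_out_of_range
    reason_missing: egfr_not_assessed
  - id: acr_range
    description: "Urine ACR >33.9 and <=565.5 mg/mmol"
    kind: lab_range
    params: {concept: acr, lo: 33.9, hi: 565.5, lo_incl: false, hi_incl: true}
    reason_fail: albuminuria_below_threshold
    reason_missing: albuminuria_not_assessed
  - id: ras_current
    description: "Current prescription for a RAS inhibitor (ACEi or ARB)"
    kind: current_rx_any
    params: {classes: [ACEi, ARB]}
    reason_fail: not_on_RAS
exclusion:
  - id: nyha_iv_hf
    description: "NYHA class IV congestive heart failure"
    kind: code_any
    params: {flags: [nyha_iv_hf]}
  - id: cirrhosis
    description: "Known significant liver disease (coded cirrhosis)"
    kind: code_any
    params: {flags: [cirrhosis]}
  - id: dialysis
    description: "Maintenance dialysis (ESKD)"
    kind: code_any
    params: {flags: [dialysis_eskd]}
  - id: kidney_transplant
    description: "Kidney transplantation"
    kind: code_any
    params: {flags: [kidney_transplant]}
  - id: t1d
    description: "Type 1 diabetes"
    kind: code_any
    params: {flags: [t1d]}
  - id: combined_acei_arb
    description: "Current prescription for both ACE inhibitor and ARB"
    kind: combined_rx
    params: {classes: [ACEi, ARB]}
not_evaluable:
  - id: recent_cv_event
    description: "Cardiovascular event shortly before enrolment (not derivable from coded primary-care data)"
  - id: immunosuppression_for_kidney_disease
    description: "Immunosuppressive treatment for primary kidney disease (not derivable)"
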