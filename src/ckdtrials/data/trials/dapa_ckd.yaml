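# DAPA-CKD enrolment criteria as operationalized against primary-care data.
# The upper urine ACR bound is carried as 565 mg/mmol, the value used in the
# emulation (the CREDENCE spec uses 565.5 for the same 5000 mg/g source).
name: DAPA-CKD
inclusion:
  - id: age_min_18
    description: ">=18 years of age"
    kind: min_age
    params: {min: 18}
    reason_fail: age
  - id: egfr_range
    description: "eGFR >=25 and <=75 mL/min/1.73 m2 (CKD-EPI 2021)"
    kind: lab_range
    params: {concept: egfr, lo: 25, hi: 75, lo_incl: true, hi_incl: true}
    reason_fail: egfr_out_of_range
    reason_missing: egfr_not_assessed
  - id: acr_range
    description: "Urine ACR >=22.6 and <=565 mg/mmol"
    kind: lab_range
    params: {concept: acr, lo: 22.6, hi: 565, lo_incl: true, hi_incl: true}
    reason_fail: albuminuria_below_threshold
    reason_missing: albuminuria_not_assessed
  - id: ras_current
    description: "Current prescription for a RAS inhibitor (ACEi or ARB)"
    kind: current_rx_any
    params: {classes: [ACEi, ARB]}
    reason_fail: not_on_RAS
exclusion:
  - id: adpkd
    description: "Autosomal dominant polycystic kidney disease"
    kind: code_any
    params: {flags: [adpkd]}
  - id: arpkd
    description: "Autosomal recessive polycystic kidney disease"
    kind: code_any
    params: {flags: [arpkd]}
  - id: lupus_nephritis
    description: "Lupus nephritis"
    kind: code_any
    params: {flags: [lupus_nephritis]}
  - id: anca_vasculitis
    description: "ANCA-associated vasculitis"
    kind: code_any
    params: {flags: [anca_vasculitis]}
  - id: organ_transplant
    description: "History of organ transplantation (any organ)"
    kind: code_any
    params: {flags: [kidney_transplant, organ_transplant_other]}
  - id: t1d
    description: "Type 1 diabetes"
    kind: code_any
    params: {flags: [t1d]}
  - id: nyha_iv_hf
    description: "NYHA class IV congestive heart failure"
    kind: code_any
    params: {flags: [nyha_iv_hf]}
not_evaluable:
  - id: recent_cv_event
    description: "Cardiovascular event within 12 weeks of enrolment (not derivable from coded primary-care data)"
  - id: recent_immunotherapy
    description: "Recent cytotoxic/immunosuppressive therapy for kidney disease (not derivable)"
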