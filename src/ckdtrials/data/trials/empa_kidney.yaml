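# EMPA-KIDNEY enrolment criteria as operationalized against primary-care data.
# The eGFR/albuminuria inclusion is a two-arm group: eGFR 20-<45 alone, or
# eGFR 45-<90 with urine ACR >=22.6 mg/mmol (or urine PCR >=33.9 mg/mmol,
# either measure qualifying).
name: EMPA-KIDNEY
inclusion:
  - id: age_min_18
    description: ">=18 years of age"
    kind: min_age
    params: {min: 18}
    reason_fail: age
  - id: ras_current
    description: "Current prescription for a RAS inhibitor (ACEi or ARB)"
    kind: current_rx_any
    params: {classes: [ACEi, ARB]}
    reason_fail: not_on_RAS
  - id: egfr_acr_groups
    description: >-
      eGFR >=20 and <45, or eGFR >=45 and <90 with urine ACR >=22.6 mg/mmol
      (or urine PCR >=33.9 mg/mmol)
    kind: egfr_acr_groups
    params:
      egfr_low_lo: 20
      egfr_low_hi: 45
      egfr_high_lo: 45
      egfr_high_hi: 90
      acr_min: 22.6
      pcr_min: 33.9
    reason_fail: egfr_out_of_range   # refined per patient during attribution
    reason_missing: egfr_not_assessed
exclusion:
  - id: t2d_ascvd_egfr_gt60
    description: "T2D with prior atherosclerotic CVD (IHD, stroke, PAD) and eGFR >60"
    kind: t2d_ascvd_egfr
    params: {egfr_gt: 60}
  - id: adpkd
    description: "Autosomal dominant polycystic kidney disease"
    kind: code_any
    params: {flags: [adpkd]}
  - id: arpkd
    description: "Autosomal recessive polycystic kidney disease"
    kind: code_any
    params: {flags: [arpkd]}
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
  - id: scheduled_transplant
    description: "Scheduled living-donor kidney transplant (not derivable from coded primary-care data)"
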