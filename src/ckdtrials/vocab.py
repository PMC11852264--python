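"""Closed vocabularies for the four EHR-like input tables.

Real primary-care records code events in SNOMED CT; this package works on a
closed concept vocabulary that covers exactly the variables the trial
eligibility criteria and the eligibility models need.
"""

from __future__ import annotations

# Observation concepts and their fixed units
CONCEPT_UNITS = {
    "serum_creatinine": "umol/L",
    "urine_acr": "mg/mmol",
    "urine_pcr": "mg/mmol",
    "hba1c": "mmol/mol",
    "sbp": "mmHg",
    "dbp": "mmHg",
    "bmi": "kg/m2",
    "weight": "kg",
    "smoking_status": "code",  # 0 never, 1 ex, 2 current
}
CONCEPTS = tuple(CONCEPT_UNITS)

# Diagnostic / event codes
CLINICAL_CODES = (
    "T1D",
    "T2D",
    "IHD",
    "stroke",
    "TIA",
    "PAD",
    "heart_failure",
    "NYHA_IV_HF",
    "cirrhosis",
    "dialysis_ESKD",
    "kidney_transplant",
    "organ_transplant_other",
    "ADPKD",
    "ARPKD",
    "lupus_nephritis",
    "ANCA_vasculitis",
    "hypertension",
    "CKD_diagnosis",
)

# code -> boolean flag column on the patient profile
CODE_FLAGS = {
    "T1D": "t1d_code",
    "T2D": "t2d_code",
    "IHD": "ihd",
    "stroke": "stroke",
    "TIA": "tia",
    "PAD": "pad",
    "heart_failure": "heart_failure",
    "NYHA_IV_HF": "nyha_iv_hf",
    "cirrhosis": "cirrhosis",
    "dialysis_ESKD": "dialysis_eskd",
    "kidney_transplant": "kidney_transplant",
    "organ_transplant_other": "organ_transplant_other",
    "ADPKD": "adpkd",
    "ARPKD": "arpkd",
    "lupus_nephritis": "lupus_nephritis",
    "ANCA_vasculitis": "anca_vasculitis",
    "hypertension": "hypertension",
    "CKD_diagnosis": "ckd_diagnosis",
}

DRUG_CLASSES = ("ACEi", "ARB", "diuretic", "statin", "SGLT2i")

ETHNICITIES = ("White", "Asian", "Black", "Mixed", "Other")

TRIALS = ("CREDENCE", "DAPA-CKD", "EMPA-KIDNEY")

SEXES = ("male", "female")

# Primary ineligibility reasons, in attribution priority order
REASON_ORDER = (
    "not_on_RAS",
    "albuminuria_below_threshold",
    "albuminuria_not_assessed",
    "egfr_out_of_range",
    "egfr_not_assessed",
    "age",
    "hba1c",
    "no_t2d",
    "exclusion_criterion",
    "other",
)
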