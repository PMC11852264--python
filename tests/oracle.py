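"""Independent brute-force re-implementation of the three trials' criteria.

Written directly from the operationalized criterion table as plain Python over
one profile dict, deliberately sharing no code with the data-driven engine.
Returns (eligible, failed_inclusion_ids, met_exclusion_ids, missing_concepts).
"""

import math


def _isnan(x):
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return x is None


def credence(p):
    failed, excl, missing = set(), set(), set()
    if not p["age"] >= 30:
        failed.add("age_min_30")
    if not p["t2d"]:
        failed.add("t2d")
    if _isnan(p["hba1c"]):
        missing.add("hba1c")
    elif not (47.5 <= p["hba1c"] <= 107.7):
        failed.add("hba1c_range")
    if _isnan(p["egfr"]):
        missing.add("egfr")
    elif not (30 <= p["egfr"] < 90):
        failed.add("egfr_range")
    if _isnan(p["acr"]):
        missing.add("acr")
    elif not (33.9 < p["acr"] <= 565.5):
        failed.add("acr_range")
    if not (p["rx_acei"] or p["rx_arb"]):
        failed.add("ras_current")
    if p["nyha_iv_hf"]:
        excl.add("nyha_iv_hf")
    if p["cirrhosis"]:
        excl.add("cirrhosis")
    if p["dialysis_eskd"]:
        excl.add("dialysis")
    if p["kidney_transplant"]:
        excl.add("kidney_transplant")
    if p["t1d_code"]:
        excl.add("t1d")
    if p["rx_acei"] and p["rx_arb"]:
        excl.add("combined_acei_arb")
    eligible = not failed and not excl and not missing
    return eligible, failed, excl, missing


def dapa_ckd(p):
    failed, excl, missing = set(), set(), set()
    if not p["age"] >= 18:
        failed.add("age_min_18")
    if _isnan(p["egfr"]):
        missing.add("egfr")
    elif not (25 <= p["egfr"] <= 75):
        failed.add("egfr_range")
    if _isnan(p["acr"]):
        missing.add("acr")
    elif not (22.6 <= p["acr"] <= 565):
        failed.add("acr_range")
    if not (p["rx_acei"] or p["rx_arb"]):
        failed.add("ras_current")
    if p["adpkd"]:
        excl.add("adpkd")
    if p["arpkd"]:
        excl.add("arpkd")
    if p["lupus_nephritis"]:
        excl.add("lupus_nephritis")
    if p["anca_vasculitis"]:
        excl.add("anca_vasculitis")
    if p["kidney_transplant"] or p["organ_transplant_other"]:
        excl.add("organ_transplant")
    if p["t1d_code"]:
        excl.add("t1d")
    if p["nyha_iv_hf"]:
        excl.add("nyha_iv_hf")
    eligible = not failed and not excl and not missing
    return eligible, failed, excl, missing


def empa_kidney(p):
    failed, excl, missing = set(), set(), set()
    if not p["age"] >= 18:
        failed.add("age_min_18")
    if not (p["rx_acei"] or p["rx_arb"]):
        failed.add("ras_current")
    egfr, acr, pcr = p["egfr"], p["acr"], p["pcr"]
    if _isnan(egfr):
        missing.add("egfr")
    else:
        low_arm = 20 <= egfr < 45
        high_band = 45 <= egfr < 90
        prot = ((not _isnan(acr) and acr >= 22.6)
                or (not _isnan(pcr) and pcr >= 33.9))
        if low_arm or (high_band and prot):
            pass
        elif high_band and _isnan(acr) and _isnan(pcr):
            missing.add("acr")
        else:
            failed.add("egfr_acr_groups")
    ascvd = p["ihd"] or p["stroke"] or p["pad"]
    if p["t2d"] and ascvd and (not _isnan(egfr)) and egfr > 60:
        excl.add("t2d_ascvd_egfr_gt60")
    if p["adpkd"]:
        excl.add("adpkd")
    if p["arpkd"]:
        excl.add("arpkd")
    if p["dialysis_eskd"]:
        excl.add("dialysis")
    if p["kidney_transplant"]:
        excl.add("kidney_transplant")
    if p["t1d_code"]:
        excl.add("t1d")
    if p["rx_acei"] and p["rx_arb"]:
        excl.add("combined_acei_arb")
    eligible = not failed and not excl and not missing
    return eligible, failed, excl, missing


ORACLES = {"CREDENCE": credence, "DAPA-CKD": dapa_ckd, "EMPA-KIDNEY": empa_kidney}
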