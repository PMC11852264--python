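import numpy as np
import pandas as pd
import pytest

from ckdtrials.phenotyping import build_ckd_register, build_profiles, clean_observations
from ckdtrials.synthetic import GeneratorConfig, generate_population

INDEX_DATE = pd.Timestamp("2022-12-31")


def days_before(n):
    return INDEX_DATE - pd.Timedelta(days=n)


def make_patient(pid="P1", sex="male", age=70.0, ethnicity="White",
                 imd=3, practice_imd=2, cmms=1.5):
    return pd.Series({
        "patient_id": pid, "sex": sex,
        "birth_date": INDEX_DATE - pd.Timedelta(days=round(age * 365.25)),
        "ethnicity": ethnicity, "imd_quintile": imd,
        "practice_imd_quintile": practice_imd, "cmms": cmms,
    })


def _with_dates(df):
    df["date"] = pd.to_datetime(df["date"])
    return df


def make_obs(rows):
    """rows: list of (patient_id, concept, value, days_before_index)."""
    return _with_dates(pd.DataFrame(
        [{"patient_id": p, "concept": c, "value": v, "date": days_before(d)}
         for p, c, v, d in rows],
        columns=["patient_id", "concept", "value", "date"],
    ))


def make_codes(rows):
    """rows: list of (patient_id, code, days_before_index)."""
    return _with_dates(pd.DataFrame(
        [{"patient_id": p, "code": c, "date": days_before(d)} for p, c, d in rows],
        columns=["patient_id", "code", "date"],
    ))


def make_rx(rows):
    """rows: list of (patient_id, drug_class, days_before_index)."""
    return _with_dates(pd.DataFrame(
        [{"patient_id": p, "drug_class": c, "date": days_before(d)} for p, c, d in rows],
        columns=["patient_id", "drug_class", "date"],
    ))


# a fully populated current profile, CREDENCE-eligible by default
PROFILE_DEFAULTS = dict(
    patient_id="PX", age=60.0, sex="male", ethnicity="White", imd_quintile=3,
    cmms=1.5, creatinine=120.0, egfr=50.0, acr=80.0, pcr=np.nan, hba1c=60.0,
    sbp=135.0, dbp=78.0, bmi=29.0, weight=85.0, smoking=0.0,
    t1d_code=False, t2d_code=True, ihd=False, stroke=False, tia=False,
    pad=False, heart_failure=False, nyha_iv_hf=False, cirrhosis=False,
    dialysis_eskd=False, kidney_transplant=False, organ_transplant_other=False,
    adpkd=False, arpkd=False, lupus_nephritis=False, anca_vasculitis=False,
    hypertension=True, ckd_diagnosis=True,
    rx_acei=True, rx_arb=False, rx_diuretic=False, rx_statin=True,
    rx_sglt2i=False, t2d=True, t1d=False, diabetes_class="T2D",
    ascvd=False, cvd=False, ras_current=True,
)


def make_profile(**overrides):
    prof = dict(PROFILE_DEFAULTS)
    prof.update(overrides)
    prof["ras_current"] = bool(prof["rx_acei"] or prof["rx_arb"])
    prof["ascvd"] = bool(prof["ihd"] or prof["stroke"] or prof["pad"])
    prof["cvd"] = bool(prof["ascvd"] or prof["tia"])
    # keep the derived diabetes classification consistent with the codes
    # (a T1D code always classifies as T1D, which takes precedence over T2D)
    prof["t1d"] = bool(prof["t1d_code"])
    if prof["t1d"]:
        prof["t2d"] = False
        prof["diabetes_class"] = "T1D"
    else:
        prof["diabetes_class"] = "T2D" if prof["t2d"] else "none"
    return pd.Series(prof)


@pytest.fixture(scope="session")
def complete_pop():
    """A complete (no-missingness) synthetic population with ground truth."""
    cfg = GeneratorConfig(n_patients=4000, seed=11)
    patients, obs, codes, rx, truth = generate_population(cfg)
    return cfg, patients, obs, codes, rx, truth


@pytest.fixture(scope="session")
def phenotyped(complete_pop):
    """(profiles of CKD patients, register, ground truth indexed by patient)."""
    cfg, patients, obs, codes, rx, truth = complete_pop
    obs = clean_observations(obs)
    register = build_ckd_register(patients, obs, codes, cfg.index_date, rx)
    profiles = build_profiles(patients, obs, codes, rx, cfg.index_date)
    ckd_ids = register.loc[register["is_ckd"], "patient_id"]
    return (profiles[profiles["patient_id"].isin(ckd_ids)],
            register.set_index("patient_id"),
            truth.set_index("patient_id"))
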