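"""CKD phenotyping from longitudinal primary-care observations.

Implements value cleaning, the race-free CKD-EPI 2021 eGFR equation, resolution
of "current" clinical values and prescriptions at an index date, the ontological
CKD case definition (diagnostic code, repeated low eGFR, or repeated
proteinuria) and a diabetes classification.

Conventions
-----------
* Serum creatinine is stored in umol/L (UK convention) and converted to mg/dL
  internally by dividing by 88.42.
* eGFR is evaluated with the patient's age at the measurement date, as a
  laboratory reporting alongside the creatinine result would.
* "Current" clinical measures are the most recent values recorded within
  2 years (730 days) before the index date; older values count as missing for
  characteristics and eligibility, but the full history is used for CKD
  ascertainment.
* A current prescription is one issued within the last 90 days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError
from .vocab import CODE_FLAGS, CONCEPTS, DRUG_CLASSES, ETHNICITIES

logger = logging.getLogger(__name__)

UMOL_PER_MGDL = 88.42
DAYS_PER_YEAR = 365.25
RECENCY_DAYS = 730          # clinical measures >= 2 years old are missing
RX_WINDOW_DAYS = 90         # current-prescription window
EGFR_CKD_THRESHOLD = 60.0
ACR_CKD_THRESHOLD = 3.0     # mg/mmol
PCR_CKD_THRESHOLD = 15.0    # mg/mmol
PAIR_GAP_DAYS = 90          # minimum spacing of repeat measurements
HBA1C_DIAGNOSTIC = 48.0     # mmol/mol, conventional diagnostic cut


def load_plausible_ranges() -> dict[str, tuple[float, float]]:
    """Shipped default plausible ranges per observation concept."""
    with resources.files("ckdtrials.data").joinpath("plausible_ranges.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}


def clean_observations(
    observations: pd.DataFrame,
    plausible_ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Remove implausible observation values (treated as missing downstream).

    Rows with values outside the concept's [lo, hi] range are dropped; in-range
    rows are returned untouched.  Removal counts are logged per concept.
    """
    ranges = plausible_ranges if plausible_ranges is not None else load_plausible_ranges()
    unknown = set(ranges) - set(CONCEPTS)
    if unknown:
        raise ConfigurationError(f"unknown concepts in plausible-range table: {sorted(unknown)}")
    keep = pd.Series(True, index=observations.index)
    for concept, (lo, hi) in ranges.items():
        mask = observations["concept"] == concept
        bad = mask & ~observations["value"].between(lo, hi)
        n_bad = int(bad.sum())
        if n_bad:
            logger.info("clean_observations: removed %d %s values outside [%s, %s]",
                        n_bad, concept, lo, hi)
        keep &= ~bad
    return observations.loc[keep].copy()


def egfr_ckdepi2021(creatinine_umol_l, age_years, sex):
    """Estimated GFR (mL/min/1.73 m2) from the CKD-EPI 2021 race-free equation.

    eGFR = 142 * min(Scr/k, 1)**alpha * max(Scr/k, 1)**-1.200
               * 0.9938**age * (1.012 if female)

    with Scr in mg/dL, k = 0.7 (female) / 0.9 (male) and
    alpha = -0.241 (female) / -0.302 (male).  Accepts scalars or arrays.
    """
    scr = np.asarray(creatinine_umol_l, dtype=float)
    age = np.asarray(age_years, dtype=float)
    female = np.asarray(sex) == "female"
    if np.any(scr <= 0):
        raise DomainError("creatinine must be positive")
    scr_mgdl = scr / UMOL_PER_MGDL
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    ratio = scr_mgdl / kappa
    egfr = (
        142.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.200
        * 0.9938 ** age
        * np.where(female, 1.012, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


def creatinine_for_egfr(egfr, age_years, sex):
    """Invert the CKD-EPI 2021 equation: creatinine (umol/L) giving a target eGFR.

    The equation is strictly decreasing and piecewise log-linear in creatinine,
    so the inverse is closed-form on each branch.
    """
    g = np.asarray(egfr, dtype=float)
    age = np.asarray(age_years, dtype=float)
    female = np.asarray(sex) == "female"
    if np.any(g <= 0):
        raise DomainError("eGFR must be positive")
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    base = 142.0 * 0.9938 ** age * np.where(female, 1.012, 1.0)
    rel = g / base  # = r**alpha if r <= 1 else r**-1.2
    low_branch = rel >= 1.0  # g above the knee value -> r <= 1
    ratio = np.where(low_branch, rel ** (1.0 / alpha), rel ** (1.0 / -1.2))
    scr_mgdl = ratio * kappa
    out = scr_mgdl * UMOL_PER_MGDL
    return out if out.ndim else float(out)


def _age_at(dates: pd.Series, birth_dates: pd.Series) -> pd.Series:
    return (dates - birth_dates).dt.days / DAYS_PER_YEAR


def _attach_egfr(observations: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Return creatinine observations with an egfr column (age at measurement)."""
    creat = observations[observations["concept"] == "serum_creatinine"]
    if creat.empty:
        return creat.assign(egfr=pd.Series(dtype=float))
    meta = patients.set_index("patient_id")[["birth_date", "sex"]]
    creat = creat.join(meta, on="patient_id")
    age = _age_at(creat["date"], creat["birth_date"])
    creat = creat.assign(egfr=egfr_ckdepi2021(creat["value"], age, creat["sex"]))
    return creat


def _has_repeat(qualifying: pd.DataFrame, min_gap_days: int = PAIR_GAP_DAYS) -> pd.Series:
    """Patients with >= 2 qualifying measurements spanning >= min_gap_days.

    A pair (both qualifying, >= gap apart) exists iff the date span of all
    qualifying measurements reaches the gap.
    """
    if qualifying.empty:
        return pd.Series(dtype=bool)
    g = qualifying.groupby("patient_id")["date"]
    span = (g.max() - g.min()).dt.days
    return span >= min_gap_days


def classify_diabetes_cohort(
    patients: pd.DataFrame,
    observations: pd.DataFrame,
    codes: pd.DataFrame,
    prescriptions: pd.DataFrame | None = None,
    glucose_lowering_classes: tuple[str, ...] = (),
) -> pd.Series:
    """Diabetes class per patient: 'T1D', 'T2D' or 'none' (T1D takes precedence).

    T2D is ascertained by a T2D diagnostic code, two HbA1c >= 48 mmol/mol at
    least 90 days apart, or (if configured) a prescription from a
    glucose-lowering drug class.  The prescription route is off by default
    because none of the modelled drug classes is diabetes-specific.
    """
    ids = patients["patient_id"]
    t1d = ids.isin(codes.loc[codes["code"] == "T1D", "patient_id"])
    t2d_code = ids.isin(codes.loc[codes["code"] == "T2D", "patient_id"])
    hba1c = observations[
        (observations["concept"] == "hba1c")
        & (observations["value"] >= HBA1C_DIAGNOSTIC)
    ]
    repeat = _has_repeat(hba1c)
    t2d_lab = ids.isin(repeat.index[repeat])
    t2d_rx = pd.Series(False, index=ids.index)
    if glucose_lowering_classes and prescriptions is not None:
        rx = prescriptions[prescriptions["drug_class"].isin(glucose_lowering_classes)]
        t2d_rx = ids.isin(rx["patient_id"])
    out = pd.Series("none", index=ids.index)
    out[(t2d_code | t2d_lab | t2d_rx).to_numpy()] = "T2D"
    out[t1d.to_numpy()] = "T1D"
    return pd.Series(out.to_numpy(), index=ids.to_numpy(), name="diabetes_class")


def classify_diabetes(codes, observations, prescriptions=None,
                      glucose_lowering_classes=()) -> str:
    """Single-patient diabetes classification (see classify_diabetes_cohort)."""
    pid = None
    for tbl in (codes, observations, prescriptions):
        if tbl is not None and len(tbl):
            pid = tbl["patient_id"].iloc[0]
            break
    if pid is None:
        return "none"
    patients = pd.DataFrame({"patient_id": [pid]})
    empty = pd.DataFrame(columns=["patient_id", "concept", "value", "date"])
    res = classify_diabetes_cohort(
        patients,
        observations if observations is not None else empty,
        codes if codes is not None else pd.DataFrame(columns=["patient_id", "code", "date"]),
        prescriptions,
        glucose_lowering_classes,
    )
    return res.loc[pid]


def build_ckd_register(
    patients: pd.DataFrame,
    observations: pd.DataFrame,
    codes: pd.DataFrame,
    index_date,
    prescriptions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Ontological CKD ascertainment over the full measurement history.

    A patient is CKD if any of three routes fires:

    * ``diagnostic_code`` -- a coded CKD diagnosis;
    * ``egfr_repeat``     -- two eGFR < 60 mL/min/1.73 m2 from creatinine
      measurements at least 90 days apart;
    * ``proteinuria_repeat`` -- two urine ACR > 3 mg/mmol, or two urine
      PCR > 15 mg/mmol, at least 90 days apart (ACR and PCR do not mix).

    Returns one row per patient with is_ckd, the satisfied routes and the
    diabetes class.  Only adults (>= 18 years at index) are considered in
    downstream cohorts; the register reports everyone it is given.
    """
    index_date = pd.Timestamp(index_date)
    obs = observations[observations["date"] <= index_date]
    ids = patients["patient_id"]

    coded = ids.isin(codes.loc[codes["code"] == "CKD_diagnosis", "patient_id"])

    creat = _attach_egfr(obs, patients)
    low = creat[creat["egfr"] < EGFR_CKD_THRESHOLD]
    rep = _has_repeat(low)
    egfr_repeat = ids.isin(rep.index[rep])

    acr = obs[(obs["concept"] == "urine_acr") & (obs["value"] > ACR_CKD_THRESHOLD)]
    pcr = obs[(obs["concept"] == "urine_pcr") & (obs["value"] > PCR_CKD_THRESHOLD)]
    rep_acr = _has_repeat(acr)
    rep_pcr = _has_repeat(pcr)
    prot_repeat = (ids.isin(rep_acr.index[rep_acr])
                   | ids.isin(rep_pcr.index[rep_pcr]))

    diabetes = classify_diabetes_cohort(patients, obs, codes, prescriptions)
    register = pd.DataFrame({
        "patient_id": ids.to_numpy(),
        "basis_code": coded.to_numpy(),
        "basis_egfr": egfr_repeat.to_numpy(),
        "basis_proteinuria": prot_repeat.to_numpy(),
        "diabetes_class": diabetes.loc[ids].to_numpy(),
    })
    register["is_ckd"] = (
        register["basis_code"] | register["basis_egfr"] | register["basis_proteinuria"]
    )
    return register


@dataclass
class CKDStatus:
    patient_id: object
    is_ckd: bool
    basis: tuple = field(default_factory=tuple)
    diabetes_class: str = "none"


def identify_ckd(patient: pd.Series, observations: pd.DataFrame,
                 codes: pd.DataFrame, index_date) -> CKDStatus:
    """Single-patient CKD ascertainment (see build_ckd_register)."""
    patients = pd.DataFrame([{
        "patient_id": patient["patient_id"],
        "birth_date": pd.Timestamp(patient["birth_date"]),
        "sex": patient["sex"],
    }])
    row = build_ckd_register(patients, observations, codes, index_date).iloc[0]
    basis = tuple(
        name for flag, name in [
            ("basis_code", "diagnostic_code"),
            ("basis_egfr", "egfr_repeat"),
            ("basis_proteinuria", "proteinuria_repeat"),
        ] if row[flag]
    )
    return CKDStatus(patient["patient_id"], bool(row["is_ckd"]), basis,
                     row["diabetes_class"])


def _latest_per_concept(obs: pd.DataFrame, index_date: pd.Timestamp) -> pd.DataFrame:
    """Most recent in-window value per patient x concept.

    Date ties are broken by input order (last record wins) with a warning.
    """
    window = obs[
        (obs["date"] <= index_date)
        & ((index_date - obs["date"]).dt.days < RECENCY_DAYS)
    ]
    if window.empty:
        return pd.DataFrame(columns=["patient_id", "concept", "value", "date"])
    dup = window.duplicated(subset=["patient_id", "concept", "date"], keep=False)
    if dup.any():
        logger.warning(
            "%d tied most-recent observations; resolved by input order (last wins)",
            int(dup.sum()),
        )
    window = window.reset_index(drop=True)
    # stable sort keeps input order within equal dates; tail(1) = last loaded
    latest = (
        window.sort_values(["patient_id", "concept", "date"], kind="stable")
        .groupby(["patient_id", "concept"], as_index=False)
        .tail(1)
    )
    return latest


def build_profiles(
    patients: pd.DataFrame,
    observations: pd.DataFrame,
    codes: pd.DataFrame,
    prescriptions: pd.DataFrame,
    index_date,
) -> pd.DataFrame:
    """Resolve the per-patient current profile at the index date.

    One row per patient: demographics with the study's missing-data
    conventions applied (missing ethnicity -> White; missing IMD quintile ->
    practice quintile), the latest in-window value and date per lab concept,
    comorbidity flags from the full coded history, current-prescription flags
    per drug class, and derived fields (age, eGFR, diabetes class, composite
    cardiovascular flags).
    """
    if index_date is None:
        raise ConfigurationError("index_date is required")
    index_date = pd.Timestamp(index_date)

    prof = patients.copy()
    prof["age"] = _age_at(pd.Series(index_date, index=prof.index), prof["birth_date"])
    eth = prof["ethnicity"].where(prof["ethnicity"].isin(ETHNICITIES))
    prof["ethnicity"] = eth.fillna("White")
    imd = pd.to_numeric(prof["imd_quintile"], errors="coerce")
    prof["imd_quintile"] = imd.fillna(prof["practice_imd_quintile"]).astype(int)
    prof = prof.drop(columns=["practice_imd_quintile"])

    latest = _latest_per_concept(observations, index_date)
    for concept in CONCEPTS:
        sub = latest[latest["concept"] == concept].set_index("patient_id")
        col = {"serum_creatinine": "creatinine", "urine_acr": "acr",
               "urine_pcr": "pcr", "smoking_status": "smoking"}.get(concept, concept)
        prof[col] = prof["patient_id"].map(sub["value"])
        prof[col + "_date"] = prof["patient_id"].map(sub["date"])

    has_cr = prof["creatinine"].notna()
    prof["egfr"] = np.nan
    if has_cr.any():
        age_meas = _age_at(prof.loc[has_cr, "creatinine_date"], prof.loc[has_cr, "birth_date"])
        prof.loc[has_cr, "egfr"] = egfr_ckdepi2021(
            prof.loc[has_cr, "creatinine"], age_meas, prof.loc[has_cr, "sex"])

    hist_codes = codes[codes["date"] <= index_date]
    for code, flag in CODE_FLAGS.items():
        prof[flag] = prof["patient_id"].isin(
            hist_codes.loc[hist_codes["code"] == code, "patient_id"]).to_numpy()

    days_ago = (index_date - prescriptions["date"]).dt.days
    current_rx = prescriptions[(days_ago >= 0) & (days_ago <= RX_WINDOW_DAYS)]
    for cls in DRUG_CLASSES:
        prof["rx_" + cls.lower()] = prof["patient_id"].isin(
            current_rx.loc[current_rx["drug_class"] == cls, "patient_id"]).to_numpy()

    diabetes = classify_diabetes_cohort(patients, observations[observations["date"] <= index_date],
                                        hist_codes, prescriptions)
    prof["diabetes_class"] = diabetes.loc[prof["patient_id"]].to_numpy()
    prof["t2d"] = prof["diabetes_class"] == "T2D"
    prof["t1d"] = prof["diabetes_class"] == "T1D"

    # composite cardiovascular flags: the EMPA-KIDNEY exclusion uses
    # atherosclerotic CVD (IHD, stroke, PAD); the eligibility models use a
    # broader coded CVD history including TIA
    prof["ascvd"] = prof["ihd"] | prof["stroke"] | prof["pad"]
    prof["cvd"] = prof["ascvd"] | prof["tia"]
    prof["ras_current"] = prof["rx_acei"] | prof["rx_arb"]
    return prof.drop(columns=["birth_date"]).set_index("patient_id", drop=False)


def resolve_current_profile(patient: pd.Series, observations, codes,
                            prescriptions, index_date) -> pd.Series:
    """Single-patient wrapper around build_profiles."""
    patients = pd.DataFrame([patient])
    return build_profiles(patients, observations, codes, prescriptions, index_date).iloc[0]
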