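"""Synthetic primary-care EHR generator with planted ground truth.

Generates the four input tables (patients, observations, clinical codes,
prescriptions) plus a ground-truth table, with the statistical structure the
eligibility analysis assumes:

* longitudinal serum creatinine, urine ACR/PCR and HbA1c series with dates;
* coded comorbidities and dated prescriptions by drug class;
* demographics with UK-style ethnicity and deprivation quintiles;
* planted CKD status, T2D status and per-trial eligibility.

Eligibility planting
--------------------
Within the CKD stratum, each trial's eligibility indicator follows a logistic
model on the patient's covariates, sharing one configurable coefficient vector
(``eligibility_model_coefficients``) with trial-specific intercepts calibrated
by root-finding so the expected eligible fractions hit the configured targets.
DAPA-CKD and EMPA-KIDNEY indicators are nested through a shared uniform latent
(DAPA-eligible implies EMPA-eligible, requiring target_D <= target_E);
CREDENCE is drawn independently, gated on T2D.  Each marginal indicator is
therefore exactly Bernoulli(logistic(b_trial + x'beta)), so the pre-specified
logistic model is correctly specified and its coefficients are recoverable.

Every realized eligibility pattern is then made true in the emitted tables by
construction: laboratory values are drawn inside safe sub-intervals of the
criterion windows (creatinine is obtained by inverting the CKD-EPI 2021
equation at the measurement-date age), prescriptions respect the 90-day
currency window, and trial-discordant patterns use trial-specific exclusion
codes (ADPKD excludes DAPA-CKD and EMPA-KIDNEY but not CREDENCE; lupus
nephritis excludes DAPA-CKD only).  On complete data, re-deriving phenotype
and eligibility reproduces the ground-truth table exactly, patient by patient.

All randomness flows from one seed through named substreams, so identical
configurations give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import ConfigurationError
from .imputation import bmi_category
from .phenotyping import creatinine_for_egfr
from .vocab import TRIALS

DEFAULT_COEFFICIENTS = {
    # log-odds effects of the pre-specified eligibility-model covariates
    "age": 0.01,
    "female": -0.58,
    "ethnicity_Asian": 0.35,
    "ethnicity_Black": 0.25,
    "ethnicity_Mixed": 0.0,
    "ethnicity_Other": 0.0,
    "imd_1": 0.0,
    "imd_2": 0.0,
    "imd_3": 0.0,
    "imd_4": 0.0,
    "bmi_underweight": -0.45,
    "bmi_overweight": 0.15,
    "bmi_obese_1": 0.25,
    "bmi_obese_2": 0.35,
    "bmi_obese_3": 0.35,
    "t2d": 0.70,
    "cvd": -0.10,
    "heart_failure": 0.30,
    "hypertension": 0.90,
    "cmms": 0.12,
    "statin": 0.40,
    "diuretic": 0.25,
}

#: generator coefficient key -> statsmodels/patsy parameter name
STATSMODELS_TERM = {
    "age": "age",
    "female": "C(sex, Treatment('male'))[T.female]",
    "ethnicity_Asian": "C(ethnicity, Treatment('White'))[T.Asian]",
    "ethnicity_Black": "C(ethnicity, Treatment('White'))[T.Black]",
    "ethnicity_Mixed": "C(ethnicity, Treatment('White'))[T.Mixed]",
    "ethnicity_Other": "C(ethnicity, Treatment('White'))[T.Other]",
    "imd_1": "C(imd_quintile, Treatment(5))[T.1]",
    "imd_2": "C(imd_quintile, Treatment(5))[T.2]",
    "imd_3": "C(imd_quintile, Treatment(5))[T.3]",
    "imd_4": "C(imd_quintile, Treatment(5))[T.4]",
    "bmi_underweight": "C(bmi_category, Treatment('normal'))[T.underweight]",
    "bmi_overweight": "C(bmi_category, Treatment('normal'))[T.overweight]",
    "bmi_obese_1": "C(bmi_category, Treatment('normal'))[T.obese_1]",
    "bmi_obese_2": "C(bmi_category, Treatment('normal'))[T.obese_2]",
    "bmi_obese_3": "C(bmi_category, Treatment('normal'))[T.obese_3]",
    "t2d": "t2d",
    "cvd": "cvd",
    "heart_failure": "heart_failure",
    "hypertension": "hypertension",
    "cmms": "cmms",
    "statin": "statin",
    "diuretic": "diuretic",
}

DEFAULT_MISSINGNESS = {
    "bmi": {"mechanism": "MAR", "rate": 0.10},
    "sbp": {"mechanism": "MAR", "rate": 0.08},
    "dbp": {"mechanism": "MAR", "rate": 0.08},
    "ethnicity": {"mechanism": "MNAR", "rate": 0.10},
    "imd_quintile": {"mechanism": "MAR", "rate": 0.03},
}

_ETHNICITY_P = (0.85, 0.06, 0.04, 0.02, 0.03)  # White, Asian, Black, Mixed, Other
_ETHNICITIES = ("White", "Asian", "Black", "Mixed", "Other")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic population.

    Defaults mirror the emulated primary-care setting: 7.7% CKD prevalence,
    32.8% of CKD with co-existing T2D, planted eligible fractions of
    0.9% / 2.2% / 8.0% for CREDENCE / DAPA-CKD / EMPA-KIDNEY, and RAS
    inhibitors prescribed to 45.1% of the CKD population.
    """
    n_patients: int = 10_000
    index_date: str = "2022-12-31"
    seed: int = 0
    ckd_prevalence: float = 0.077
    t2d_given_ckd: float = 0.328
    t2d_non_ckd: float = 0.08
    target_eligible_fraction: dict = field(default_factory=lambda: {
        "CREDENCE": 0.009, "DAPA-CKD": 0.022, "EMPA-KIDNEY": 0.080})
    albuminuria_assessed_fraction: float = 0.70
    ras_prescribed_fraction: float = 0.451
    missingness: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_MISSINGNESS.items()})
    stale_measure_fraction: float | dict = 0.08
    eligibility_model_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        fracs = {
            "ckd_prevalence": self.ckd_prevalence,
            "t2d_given_ckd": self.t2d_given_ckd,
            "t2d_non_ckd": self.t2d_non_ckd,
            "albuminuria_assessed_fraction": self.albuminuria_assessed_fraction,
            "ras_prescribed_fraction": self.ras_prescribed_fraction,
            **{f"target[{k}]": v for k, v in self.target_eligible_fraction.items()},
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]; got {value}")
        unknown = set(self.target_eligible_fraction) - set(TRIALS)
        if unknown:
            raise ConfigurationError(f"unknown trials in targets: {sorted(unknown)}")
        f_d = self.target_eligible_fraction.get("DAPA-CKD", 0.0)
        f_e = self.target_eligible_fraction.get("EMPA-KIDNEY", 0.0)
        if f_d > f_e:
            raise ConfigurationError(
                "the DAPA-CKD target cannot exceed the EMPA-KIDNEY target "
                "(DAPA-eligible patients are planted as a subset of EMPA-eligible)")
        for var, spec in self.missingness.items():
            if spec.get("mechanism") not in ("MAR", "MNAR"):
                raise ConfigurationError(f"missingness mechanism for {var} must be MAR or MNAR")
            if not 0.0 <= spec.get("rate", 0.0) <= 1.0:
                raise ConfigurationError(f"missingness rate for {var} must lie in [0, 1]")
        stale = self.stale_measure_fraction
        values = stale.values() if isinstance(stale, dict) else [stale]
        for v in values:
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError("stale_measure_fraction must lie in [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _linear_predictor(cov: pd.DataFrame, coef: dict) -> np.ndarray:
    """x'beta for the eligibility model covariates (no intercept)."""
    eta = np.zeros(len(cov))
    eta += coef.get("age", 0.0) * cov["age"].to_numpy()
    eta += coef.get("female", 0.0) * (cov["sex"].to_numpy() == "female")
    for eth in ("Asian", "Black", "Mixed", "Other"):
        eta += coef.get(f"ethnicity_{eth}", 0.0) * (cov["ethnicity"].to_numpy() == eth)
    for q in (1, 2, 3, 4):
        eta += coef.get(f"imd_{q}", 0.0) * (cov["imd_quintile"].to_numpy() == q)
    cats = cov["bmi_category"].to_numpy()
    for cat in ("underweight", "overweight", "obese_1", "obese_2", "obese_3"):
        eta += coef.get(f"bmi_{cat}", 0.0) * (cats == cat)
    for flag in ("t2d", "cvd", "heart_failure", "hypertension", "statin", "diuretic"):
        eta += coef.get(flag, 0.0) * cov[flag].to_numpy().astype(float)
    eta += coef.get("cmms", 0.0) * cov["cmms"].to_numpy()
    return eta


def _calibrate_intercept(eta: np.ndarray, target: float,
                         gate: np.ndarray | None = None) -> float:
    """Solve mean(gate * expit(b + eta)) = target for the intercept b."""
    if target <= 0:
        return -np.inf
    g = np.ones_like(eta) if gate is None else gate.astype(float)
    if target >= g.mean():
        raise ConfigurationError(
            f"target eligible fraction {target} is unattainable (gate share {g.mean():.3f})")

    def f(b):
        return float(np.mean(g * expit(b + eta))) - target

    return brentq(f, -40.0, 15.0, xtol=1e-12)


@dataclass
class TrajectoryParams:
    """Shape of a generic longitudinal lab series."""
    baseline: float
    drift_per_year: float = 0.0
    noise_sd: float = 0.0
    n_points: int = 3
    mean_interval_days: float = 180.0


def generate_lab_series(patient: pd.Series, concept: str,
                        trajectory_params: TrajectoryParams,
                        rng: np.random.Generator,
                        end_date="2022-12-31") -> pd.DataFrame:
    """One patient's dated series for a concept from a linear-drift model.

    Visit gaps follow a renewal process (uniform on 0.6-1.4 times the mean
    interval); values are baseline + drift * t + Gaussian noise, floored just
    above zero.  Negative noise SD is a configuration error (zero gives a
    deterministic series).
    """
    p = trajectory_params
    if p.noise_sd < 0:
        raise ConfigurationError("noise SD must be non-negative")
    if p.n_points < 1 or p.mean_interval_days <= 0:
        raise ConfigurationError("need n_points >= 1 and a positive visit interval")
    end = pd.Timestamp(end_date)
    gaps = rng.uniform(0.6, 1.4, size=p.n_points - 1) * p.mean_interval_days
    offsets = np.concatenate([[rng.uniform(10, 120)], gaps]).cumsum()[::-1]
    dates = end - pd.to_timedelta(np.round(offsets), unit="D")
    t_years = (dates - dates[0]).days / 365.25
    values = p.baseline + p.drift_per_year * t_years + rng.normal(0, p.noise_sd, p.n_points)
    values = np.maximum(values, 1e-3)
    return pd.DataFrame({
        "patient_id": patient["patient_id"], "concept": concept,
        "value": np.round(values, 2), "date": dates,
    })


def _pattern_recipes(ckd: pd.DataFrame, cfg: GeneratorConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Per-CKD-patient lab/code/prescription recipe realizing its (C, D, E) pattern.

    Returns columns: egfr_lo, egfr_hi, acr_lo, acr_hi, acr_present, ras,
    lupus, adpkd, ktx, prot_route (bool: CKD carried by mild proteinuria with
    eGFR above 60).
    """
    n = len(ckd)
    C = ckd["elig_credence"].to_numpy()
    D = ckd["elig_dapa"].to_numpy()
    E = ckd["elig_empa"].to_numpy()
    t2d = ckd["t2d"].to_numpy()
    cap = t2d & ckd["cvd"].to_numpy()  # eGFR > 60 would fire the EMPA T2D+ASCVD exclusion

    r = pd.DataFrame(index=ckd.index)
    r["egfr_lo"], r["egfr_hi"] = 30.5, 59.0
    r["acr_lo"], r["acr_hi"] = 1.0, 21.5
    r["acr_present"] = True
    r["ras"] = C | D | E
    for col in ("lupus", "adpkd", "ktx", "prot_route"):
        r[col] = False

    hi_unless_cap = np.where(cap, 59.5, 69.0)

    m = C & D & E
    r.loc[m, "egfr_lo"] = 31.0
    r.loc[m, "egfr_hi"] = hi_unless_cap[m]
    r.loc[m, ["acr_lo", "acr_hi"]] = (35.0, 300.0)

    m = C & ~D & E
    r.loc[m, ["egfr_lo", "egfr_hi"]] = (31.0, 59.5)
    r.loc[m, ["acr_lo", "acr_hi"]] = (35.0, 300.0)
    r.loc[m, "lupus"] = True

    m = C & ~D & ~E
    r.loc[m, ["egfr_lo", "egfr_hi"]] = (31.0, 69.0)
    r.loc[m, ["acr_lo", "acr_hi"]] = (35.0, 300.0)
    r.loc[m, "adpkd"] = True

    m = ~C & D & E
    r.loc[m, "egfr_lo"] = 25.5
    r.loc[m, "egfr_hi"] = hi_unless_cap[m]
    r.loc[m, "acr_lo"] = 23.0
    r.loc[m, "acr_hi"] = np.where(t2d[m], 33.5, 300.0)

    m = ~C & ~D & E
    r.loc[m, ["egfr_lo", "egfr_hi"]] = (20.5, 24.5)
    r.loc[m, ["acr_lo", "acr_hi"]] = (4.0, 200.0)

    # ineligible patients: mix of no-RAS, low-albuminuria-on-RAS,
    # proteinuria-route CKD with preserved eGFR, and coded exclusions
    none = ~C & ~D & ~E
    n_elig = int((~none).sum())
    n_none = int(none.sum())
    if n_none:
        p_ras_rest = np.clip(
            (cfg.ras_prescribed_fraction * n - n_elig) / n_none, 0.0, 1.0)
        u = rng.random(n)
        ras000 = none & (u < p_ras_rest)
        r.loc[ras000, "ras"] = True

        v = rng.random(n)
        excl = ras000 & (v < 0.08)
        r.loc[excl, ["egfr_lo", "egfr_hi"]] = (31.0, 44.0)
        r.loc[excl, ["acr_lo", "acr_hi"]] = (35.0, 250.0)
        r.loc[excl, "ktx"] = True

        prot = ras000 & ~excl & (v < 0.08 + 0.30)
        r.loc[prot, ["egfr_lo", "egfr_hi"]] = (61.5, 88.0)
        r.loc[prot, ["acr_lo", "acr_hi"]] = (3.3, 20.0)
        r.loc[prot, "prot_route"] = True

        normal = ras000 & ~excl & ~prot
        r.loc[normal, ["egfr_lo", "egfr_hi"]] = (45.5, 59.0)

        # high-but-subthreshold albuminuria for some no-RAS patients
        noras = none & ~ras000
        high = noras & (rng.random(n) < 0.4)
        r.loc[high, ["acr_lo", "acr_hi"]] = (35.0, 250.0)

    # albuminuria assessment: forced where the pattern requires a recorded ACR,
    # thinned among the rest towards the configured assessed fraction
    required = (C | D | r["ktx"].to_numpy() | r["prot_route"].to_numpy())
    n_req = int(required.sum())
    optional = ~required
    n_opt = int(optional.sum())
    if n_opt:
        p_present = np.clip(
            (cfg.albuminuria_assessed_fraction * n - n_req) / n_opt, 0.0, 1.0)
        r.loc[optional & (rng.random(n) >= p_present), "acr_present"] = False
    return r


def generate_population(config: GeneratorConfig):
    """Generate (patients, observations, codes, prescriptions, ground_truth).

    The emitted tables are complete (no missingness); apply
    :func:`inject_missingness` to impose the configured MAR/MNAR gaps and
    staleness.  Re-running with the same config reproduces identical tables.
    """
    config.validate()
    index_date = pd.Timestamp(config.index_date)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("demo", "eligibility", "labs", "codes", "rx"),
            np.random.SeedSequence(config.seed).spawn(5))
    }
    n = config.n_patients
    rng = streams["demo"]

    is_ckd = rng.random(n) < config.ckd_prevalence
    sex = np.where(rng.random(n) < np.where(is_ckd, 0.542, 0.505), "female", "male")
    age = np.where(
        is_ckd,
        _truncnorm(rng, 73.0, 13.0, 30.1, 95.0, n),
        _truncnorm(rng, 52.0, 18.0, 18.2, 95.0, n),
    )
    ethnicity = rng.choice(_ETHNICITIES, size=n, p=_ETHNICITY_P)
    imd = rng.integers(1, 6, size=n)
    practice_imd = rng.integers(1, 6, size=n)
    cmms = np.round(rng.gamma(2.0, 1.0, size=n), 2)
    t2d = rng.random(n) < np.where(is_ckd, config.t2d_given_ckd, config.t2d_non_ckd)
    cvd = rng.random(n) < np.where(is_ckd, 0.35, 0.12)
    hf = rng.random(n) < np.where(is_ckd, 0.13, 0.03)
    htn = rng.random(n) < np.where(is_ckd, 0.68, 0.30)
    bmi = np.round(np.clip(rng.normal(29.3, 6.0, n), 15.0, 55.0), 1)
    statin = rng.random(n) < (0.35 + 0.25 * t2d)
    diuretic = rng.random(n) < (0.25 + 0.10 * hf)
    smoking = rng.choice([0, 1, 2], size=n, p=(0.55, 0.38, 0.07))

    cov = pd.DataFrame({
        "age": age, "sex": sex, "ethnicity": ethnicity, "imd_quintile": imd,
        "bmi": bmi, "bmi_category": bmi_category(bmi).to_numpy(),
        "t2d": t2d, "cvd": cvd, "heart_failure": hf, "hypertension": htn,
        "cmms": cmms, "statin": statin, "diuretic": diuretic,
    })

    # --- eligibility planting on the CKD stratum --------------------------
    elig_c = np.zeros(n, dtype=bool)
    elig_d = np.zeros(n, dtype=bool)
    elig_e = np.zeros(n, dtype=bool)
    ckd_idx = np.flatnonzero(is_ckd)
    if ckd_idx.size:
        coef = config.eligibility_model_coefficients
        eta = _linear_predictor(cov.iloc[ckd_idx], coef)
        f = config.target_eligible_fraction
        b_e = _calibrate_intercept(eta, f.get("EMPA-KIDNEY", 0.0))
        b_d = _calibrate_intercept(eta, f.get("DAPA-CKD", 0.0))
        gate = t2d[ckd_idx]
        b_c = _calibrate_intercept(eta, f.get("CREDENCE", 0.0), gate=gate)
        rng_e = streams["eligibility"]
        u = rng_e.random(ckd_idx.size)
        u_c = rng_e.random(ckd_idx.size)
        with np.errstate(invalid="ignore"):
            elig_e[ckd_idx] = u < expit(b_e + eta) if np.isfinite(b_e) else False
            elig_d[ckd_idx] = u < expit(b_d + eta) if np.isfinite(b_d) else False
            elig_c[ckd_idx] = gate & (u_c < expit(b_c + eta)) if np.isfinite(b_c) else False

    # --- patients table ----------------------------------------------------
    ids = np.array([f"P{i:07d}" for i in range(n)])
    birth_date = index_date - pd.to_timedelta(np.round(age * 365.25), unit="D")
    patients = pd.DataFrame({
        "patient_id": ids, "sex": sex, "birth_date": birth_date,
        "ethnicity": ethnicity, "imd_quintile": imd.astype(float),
        "practice_imd_quintile": practice_imd, "cmms": cmms,
    })

    # --- lab recipes and series --------------------------------------------
    rng_l = streams["labs"]
    obs_parts = []

    ckd = pd.DataFrame({
        "patient_id": ids[ckd_idx],
        "t2d": t2d[ckd_idx], "cvd": cvd[ckd_idx],
        "elig_credence": elig_c[ckd_idx], "elig_dapa": elig_d[ckd_idx],
        "elig_empa": elig_e[ckd_idx],
    }, index=ckd_idx)
    recipes = _pattern_recipes(ckd, config, rng_l) if ckd_idx.size else None

    def emit(pid, concept, values, offsets_days):
        dates = index_date - pd.to_timedelta(np.round(offsets_days), unit="D")
        obs_parts.append(pd.DataFrame({
            "patient_id": pid, "concept": concept,
            "value": values, "date": dates}))

    # creatinine: three visits for CKD patients (>= 90-day spacing), two otherwise
    if ckd_idx.size:
        k = ckd_idx.size
        lo = recipes["egfr_lo"].to_numpy()
        hi = recipes["egfr_hi"].to_numpy()
        d3 = rng_l.uniform(15, 360, k)
        d2 = d3 + rng_l.uniform(95, 200, k)
        d1 = d2 + rng_l.uniform(95, 200, k)
        for off in (d1, d2, d3):
            g = rng_l.uniform(lo, hi)
            age_at = age[ckd_idx] - off / 365.25
            cr = np.round(creatinine_for_egfr(g, age_at, sex[ckd_idx]), 1)
            emit(ids[ckd_idx], "serum_creatinine", cr, off)

    non_idx = np.flatnonzero(~is_ckd)
    if non_idx.size:
        k = non_idx.size
        d2 = rng_l.uniform(15, 500, k)
        d1 = d2 + rng_l.uniform(95, 300, k)
        # preserved kidney function, with an age-declining ceiling so the
        # inverted creatinine stays inside the plausible range
        hi = np.minimum(108.0, 150.0 - 0.75 * age[non_idx])
        for off in (d1, d2):
            g = rng_l.uniform(63.0, hi, k)
            age_at = age[non_idx] - off / 365.25
            cr = np.round(creatinine_for_egfr(g, age_at, sex[non_idx]), 1)
            emit(ids[non_idx], "serum_creatinine", cr, off)

    # urine ACR: pairs >= 90 days apart where assessed
    if ckd_idx.size:
        present = recipes["acr_present"].to_numpy()
        sub = np.flatnonzero(present)
        if sub.size:
            pid = ids[ckd_idx][sub]
            alo = recipes["acr_lo"].to_numpy()[sub]
            ahi = recipes["acr_hi"].to_numpy()[sub]
            d_late = rng_l.uniform(20, 330, sub.size)
            d_early = d_late + rng_l.uniform(95, 250, sub.size)
            for off in (d_early, d_late):
                emit(pid, "urine_acr", np.round(rng_l.uniform(alo, ahi), 1), off)
        # mild proteinuria route: PCR pairs below every trial threshold
        prot = np.flatnonzero(recipes["prot_route"].to_numpy()
                              & (rng_l.random(ckd_idx.size) < 0.5))
        if prot.size:
            pid = ids[ckd_idx][prot]
            d_late = rng_l.uniform(20, 330, prot.size)
            d_early = d_late + rng_l.uniform(95, 250, prot.size)
            for off in (d_early, d_late):
                emit(pid, "urine_pcr", np.round(rng_l.uniform(16.0, 32.0, prot.size), 1), off)
    if non_idx.size:
        assessed = np.flatnonzero(rng_l.random(non_idx.size) < 0.35)
        if assessed.size:
            pid = ids[non_idx][assessed]
            emit(pid, "urine_acr",
                 np.round(rng_l.uniform(0.3, 2.8, assessed.size), 1),
                 rng_l.uniform(20, 500, assessed.size))

    # HbA1c: diagnostic pairs for T2D, occasional normal value otherwise
    t2d_idx = np.flatnonzero(t2d)
    if t2d_idx.size:
        pid = ids[t2d_idx]
        d_late = rng_l.uniform(20, 330, t2d_idx.size)
        d_early = d_late + rng_l.uniform(95, 250, t2d_idx.size)
        for off in (d_early, d_late):
            vals = np.round(np.clip(rng_l.normal(60, 10, t2d_idx.size), 48.5, 100.0), 1)
            emit(pid, "hba1c", vals, off)
    nrm = np.flatnonzero(~t2d & (rng_l.random(n) < 0.5))
    if nrm.size:
        emit(ids[nrm], "hba1c",
             np.round(rng_l.uniform(30, 46, nrm.size), 1),
             rng_l.uniform(20, 500, nrm.size))

    # single current measures: BMI / weight / BP / smoking
    emit(ids, "bmi", bmi, rng_l.uniform(20, 400, n))
    weight = np.round(bmi * 1.7 ** 2 * rng_l.uniform(0.9, 1.1, n), 1)
    emit(ids, "weight", weight, rng_l.uniform(20, 400, n))
    emit(ids, "sbp", np.round(np.clip(rng_l.normal(136, 17, n), 80, 230), 0),
         rng_l.uniform(20, 400, n))
    emit(ids, "dbp", np.round(np.clip(rng_l.normal(76, 11, n), 40, 140), 0),
         rng_l.uniform(20, 400, n))
    emit(ids, "smoking_status", smoking.astype(float), rng_l.uniform(20, 400, n))

    observations = pd.concat(obs_parts, ignore_index=True)
    observations = observations.sort_values(
        ["patient_id", "concept", "date"], kind="stable").reset_index(drop=True)

    # --- clinical codes -----------------------------------------------------
    rng_c = streams["codes"]
    code_parts = []

    def emit_codes(mask_or_idx, code, lo=400, hi=3000):
        idx_arr = np.flatnonzero(mask_or_idx) if mask_or_idx.dtype == bool else mask_or_idx
        if idx_arr.size == 0:
            return
        code_parts.append(pd.DataFrame({
            "patient_id": ids[idx_arr], "code": code,
            "date": index_date - pd.to_timedelta(
                np.round(rng_c.uniform(lo, hi, idx_arr.size)), unit="D"),
        }))

    emit_codes(t2d, "T2D")
    emit_codes(htn, "hypertension")
    emit_codes(hf, "heart_failure")
    cvd_idx = np.flatnonzero(cvd)
    if cvd_idx.size:
        subtype = rng_c.choice(["IHD", "stroke", "TIA", "PAD"], size=cvd_idx.size)
        for st_name in ("IHD", "stroke", "TIA", "PAD"):
            emit_codes(cvd_idx[subtype == st_name], st_name)
        second = cvd_idx[rng_c.random(cvd_idx.size) < 0.3]
        if second.size:
            subtype2 = rng_c.choice(["IHD", "stroke", "TIA", "PAD"], size=second.size)
            for st_name in ("IHD", "stroke", "TIA", "PAD"):
                emit_codes(second[subtype2 == st_name], st_name)

    if ckd_idx.size:
        emit_codes(ckd_idx[rng_c.random(ckd_idx.size) < 0.6], "CKD_diagnosis")
        emit_codes(ckd_idx[recipes["lupus"].to_numpy()], "lupus_nephritis")
        emit_codes(ckd_idx[recipes["adpkd"].to_numpy()], "ADPKD")
        emit_codes(ckd_idx[recipes["ktx"].to_numpy()], "kidney_transplant")
        none_pattern = ~(elig_c | elig_d | elig_e)[ckd_idx]
        pool = ckd_idx[none_pattern]
        if pool.size:
            u = rng_c.random(pool.size)
            emit_codes(pool[u < 0.02], "cirrhosis")
            emit_codes(pool[(u >= 0.02) & (u < 0.04)], "dialysis_ESKD")
            emit_codes(pool[(u >= 0.04) & (u < 0.05)], "organ_transplant_other")
            emit_codes(pool[(u >= 0.05) & (u < 0.055)], "ANCA_vasculitis")
            emit_codes(pool[(u >= 0.055) & (u < 0.057)], "ARPKD")
            emit_codes(pool[(u >= 0.057) & (u < 0.062)], "ADPKD")
            emit_codes(pool[(u >= 0.062) & (u < 0.065)], "lupus_nephritis")
            # T1D only among non-T2D ineligible patients (T1D takes precedence
            # in classification, so planting it elsewhere would corrupt truth)
            t1d_pool = pool[~t2d[pool]]
            if t1d_pool.size:
                emit_codes(t1d_pool[rng_c.random(t1d_pool.size) < 0.01], "T1D")
            hf_pool = pool[hf[pool]]
            if hf_pool.size:
                emit_codes(hf_pool[rng_c.random(hf_pool.size) < 0.15], "NYHA_IV_HF")

    codes = (pd.concat(code_parts, ignore_index=True)
             if code_parts else pd.DataFrame(columns=["patient_id", "code", "date"]))
    codes = codes.sort_values(["patient_id", "code", "date"],
                              kind="stable").reset_index(drop=True)

    # --- prescriptions -------------------------------------------------------
    rng_r = streams["rx"]
    rx_parts = []

    def emit_rx(idx_arr, cls, lo, hi):
        if idx_arr.size == 0:
            return
        rx_parts.append(pd.DataFrame({
            "patient_id": ids[idx_arr], "drug_class": cls,
            "date": index_date - pd.to_timedelta(
                np.round(rng_r.uniform(lo, hi, idx_arr.size)), unit="D"),
        }))

    ras = np.zeros(n, dtype=bool)
    if ckd_idx.size:
        ras[ckd_idx] = recipes["ras"].to_numpy()
    ras_non = np.flatnonzero(~is_ckd & (rng_r.random(n) < 0.25))
    ras_idx = np.union1d(np.flatnonzero(ras), ras_non)
    use_acei = rng_r.random(ras_idx.size) < 0.6
    emit_rx(ras_idx[use_acei], "ACEi", 5, 85)
    emit_rx(ras_idx[~use_acei], "ARB", 5, 85)
    # lapsed RAS prescriptions test the 90-day currency window
    no_ras = np.flatnonzero(~np.isin(np.arange(n), ras_idx))
    lapsed = no_ras[rng_r.random(no_ras.size) < 0.3]
    emit_rx(lapsed, "ACEi", 120, 700)
    if ckd_idx.size:
        none_ras = ckd_idx[(~(elig_c | elig_d | elig_e)[ckd_idx]) & ras[ckd_idx]]
        dual = none_ras[rng_r.random(none_ras.size) < 0.03]
        if dual.size:
            emit_rx(dual, "ACEi", 5, 85)
            emit_rx(dual, "ARB", 5, 85)

    emit_rx(np.flatnonzero(statin), "statin", 5, 85)
    emit_rx(np.flatnonzero(~statin & (rng_r.random(n) < 0.1)), "statin", 120, 700)
    emit_rx(np.flatnonzero(diuretic), "diuretic", 5, 85)
    emit_rx(np.flatnonzero(t2d & (rng_r.random(n) < 0.12)), "SGLT2i", 5, 85)

    prescriptions = (pd.concat(rx_parts, ignore_index=True)
                     if rx_parts else pd.DataFrame(columns=["patient_id", "drug_class", "date"]))
    prescriptions = prescriptions.sort_values(
        ["patient_id", "drug_class", "date"], kind="stable").reset_index(drop=True)

    ground_truth = pd.DataFrame({
        "patient_id": ids, "is_ckd": is_ckd, "has_t2d": t2d,
        "eligible_CREDENCE": elig_c, "eligible_DAPA-CKD": elig_d,
        "eligible_EMPA-KIDNEY": elig_e,
    })
    # planted T1D overrides the T2D covariate nowhere (only non-T2D get T1D)
    return patients, observations, codes, prescriptions, ground_truth


def inject_missingness(observations: pd.DataFrame, patients: pd.DataFrame,
                       config: GeneratorConfig):
    """Impose the configured missingness and staleness on complete tables.

    * clinical measures listed with mechanism MAR are gapped with probability
      depending only on observed covariates (sex);
    * clinical measures with mechanism MNAR are gapped preferentially at high
      values;
    * ethnicity is MNAR: non-White patients are 2.5 times as likely to lose
      their recorded ethnicity (re-normalised to the configured overall rate);
    * IMD quintile is gapped MAR (the practice quintile remains available);
    * a configured fraction of each core lab concept's series is back-dated
      so the most recent value falls more than 2 years before the index date.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 909)))
    obs = observations.copy()
    pats = patients.copy()
    concept_alias = {"bmi": "bmi", "sbp": "sbp", "dbp": "dbp", "weight": "weight",
                     "hba1c": "hba1c", "smoking_status": "smoking_status",
                     "urine_acr": "urine_acr", "urine_pcr": "urine_pcr",
                     "serum_creatinine": "serum_creatinine"}
    female = pats.set_index("patient_id")["sex"] == "female"

    for var, spec in config.missingness.items():
        rate = float(spec.get("rate", 0.0))
        if rate <= 0:
            continue
        mech = spec["mechanism"]
        if var == "ethnicity":
            non_white = (pats["ethnicity"] != "White").to_numpy()
            share_nw = non_white.mean()
            p_nw = min(1.0, 2.5 * rate)
            p_w = 0.0 if share_nw >= 1.0 else max(
                0.0, (rate - share_nw * p_nw) / (1.0 - share_nw))
            p = np.where(non_white, p_nw, p_w)
            pats.loc[rng.random(len(pats)) < p, "ethnicity"] = np.nan
        elif var == "imd_quintile":
            pats.loc[rng.random(len(pats)) < rate, "imd_quintile"] = np.nan
        elif var in concept_alias:
            concept = concept_alias[var]
            mask = obs["concept"] == concept
            if mech == "MAR":
                # patient-level gap, probability depending on observed sex only
                pids = obs.loc[mask, "patient_id"].unique()
                w = np.where(female.reindex(pids).fillna(False), 1.3, 1.0)
                p = np.clip(rate * w / w.mean(), 0.0, 1.0)
                dropped = set(pids[rng.random(pids.size) < p])
                obs = obs[~(mask & obs["patient_id"].isin(dropped))]
            else:  # MNAR: higher values more likely to be absent
                vals = obs.loc[mask, "value"]
                med = vals.median()
                w = np.where(vals > med, 1.5, 0.5)
                p = np.clip(rate * w / w.mean(), 0.0, 1.0)
                drop_rows = vals.index[rng.random(len(vals)) < p]
                obs = obs.drop(index=drop_rows)
        else:
            raise ConfigurationError(f"unknown missingness variable {var!r}")

    stale = config.stale_measure_fraction
    stale_map = stale if isinstance(stale, dict) else {
        c: stale for c in ("serum_creatinine", "urine_acr", "urine_pcr", "hba1c")}
    index_date = pd.Timestamp(config.index_date)
    for concept, frac in stale_map.items():
        if frac <= 0:
            continue
        mask = obs["concept"] == concept
        pids = obs.loc[mask, "patient_id"].unique()
        chosen = set(pids[rng.random(pids.size) < frac])
        rows = mask & obs["patient_id"].isin(chosen)
        if not rows.any():
            continue
        latest = obs.loc[rows].groupby("patient_id")["date"].max()
        days_old = (index_date - latest).dt.days
        extra = pd.Series(
            np.round(rng.uniform(5, 200, len(latest))), index=latest.index)
        shift = (730 - days_old + extra).clip(lower=0)
        obs.loc[rows, "date"] = obs.loc[rows, "date"] - pd.to_timedelta(
            obs.loc[rows, "patient_id"].map(shift), unit="D")

    return obs.reset_index(drop=True), pats


def write_tables(outdir, patients, observations, codes, prescriptions,
                 ground_truth=None) -> None:
    """Write the generated tables as comma-separated text with ISO-8601 dates."""
    import os
    os.makedirs(outdir, exist_ok=True)
    for name, df in [("patients", patients), ("observations", observations),
                     ("codes", codes), ("prescriptions", prescriptions),
                     ("ground_truth", ground_truth)]:
        if df is None:
            continue
        out = df.copy()
        for col in out.columns:
            if np.issubdtype(out[col].dtype, np.datetime64):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(f"{outdir}/{name}.csv", index=False)


def read_tables(indir):
    """Read the four tables (plus ground truth if present) written by write_tables."""
    import os
    out = []
    for name, datecols in [("patients", ["birth_date"]), ("observations", ["date"]),
                           ("codes", ["date"]), ("prescriptions", ["date"])]:
        out.append(pd.read_csv(f"{indir}/{name}.csv", parse_dates=datecols))
    gt_path = f"{indir}/ground_truth.csv"
    out.append(pd.read_csv(gt_path) if os.path.exists(gt_path) else None)
    return tuple(out)
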