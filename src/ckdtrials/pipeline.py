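"""End-to-end orchestration: tables in, report bundle out.

Stages: load or generate the four input tables -> validate -> clean -> CKD
register -> current profiles -> per-trial eligibility audit, rates and
ineligibility reasons -> baseline comparisons with standardized differences ->
multiply-imputed pooled logistic eligibility models -> complete-case
sensitivity rerun -> machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import compare_to_trial, load_trial_arm_summaries, summarize_cohort
from .eligibility import (assess_cohort, attribute_primary_reasons,
                          eligibility_rates, load_all_trial_specs,
                          ras_albuminuria_crosstab, reason_table)
from .errors import ConfigurationError, DataError
from .imputation import (bmi_category, complete_case_filter,
                         fit_eligibility_model, mice_impute, pool_rubin)
from .phenotyping import build_ckd_register, build_profiles, clean_observations
from .synthetic import GeneratorConfig, generate_population, inject_missingness, write_tables
from .vocab import CLINICAL_CODES, CONCEPTS, DRUG_CLASSES, TRIALS

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = {
    "patients": ["patient_id", "sex", "birth_date", "ethnicity",
                 "imd_quintile", "practice_imd_quintile", "cmms"],
    "observations": ["patient_id", "concept", "value", "date"],
    "codes": ["patient_id", "code", "date"],
    "prescriptions": ["patient_id", "drug_class", "date"],
}


@dataclass
class RunConfig:
    """Structured configuration for one pipeline run."""
    index_date: str = "2022-12-31"
    seed: int = 0
    output_dir: str = "results/run"
    trials: tuple = TRIALS
    input_dir: str | None = None
    synthetic: dict | None = None
    imputation_m: int = 5
    imputation_iterations: int = 5
    apply_missingness: bool = True
    fit_models: bool = True

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of input_dir / synthetic block must be set")
        pd.Timestamp(self.index_date)  # parseable

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def validate_inputs(tables: dict[str, pd.DataFrame], index_date=None) -> pd.DataFrame:
    """Schema, vocabulary and date checks over the four input tables.

    Returns a findings table with a ``level`` column: ``hard`` findings make
    the run unusable; ``warning`` rows are excluded downstream but do not stop
    the pipeline.
    """
    findings = []

    def add(level, table, message):
        findings.append({"level": level, "table": table, "message": message})

    for name, required in _REQUIRED_COLUMNS.items():
        if name not in tables:
            add("hard", name, "table missing")
            continue
        missing = [c for c in required if c not in tables[name].columns]
        if missing:
            add("hard", name, f"missing mandatory columns: {missing}")

    def check_vocab(name, col, allowed):
        if name not in tables or col not in tables[name].columns:
            return
        bad = tables[name].loc[~tables[name][col].isin(allowed), col]
        for row, value in bad.items():
            add("hard", name, f"row {row}: unknown {col} {value!r}")

    check_vocab("observations", "concept", set(CONCEPTS))
    check_vocab("codes", "code", set(CLINICAL_CODES))
    check_vocab("prescriptions", "drug_class", set(DRUG_CLASSES))
    if "patients" in tables and "sex" in tables["patients"].columns:
        check_vocab("patients", "sex", {"male", "female"})

    if index_date is not None:
        idx = pd.Timestamp(index_date)
        for name in ("observations", "codes", "prescriptions"):
            if name in tables and "date" in tables[name].columns:
                n_future = int((tables[name]["date"] > idx).sum())
                if n_future:
                    add("warning", name,
                        f"{n_future} rows dated after the index date (excluded downstream)")
    return pd.DataFrame(findings, columns=["level", "table", "message"])


# variable specs used for the trial-style baseline summaries, per trial
_COMMON_SPECS = [
    {"variable": "age", "kind": "mean_sd", "column": "age"},
    {"variable": "female", "kind": "proportion", "column": "sex", "level": "female"},
    {"variable": "ethnicity_white", "kind": "proportion", "column": "ethnicity", "level": "White"},
    {"variable": "ethnicity_asian", "kind": "proportion", "column": "ethnicity", "level": "Asian"},
    {"variable": "ethnicity_black", "kind": "proportion", "column": "ethnicity", "level": "Black"},
    {"variable": "ethnicity_mixed", "kind": "proportion", "column": "ethnicity", "level": "Mixed"},
    {"variable": "ethnicity_other", "kind": "proportion", "column": "ethnicity", "level": "Other"},
    {"variable": "current_smoker", "kind": "proportion", "column": "smoking", "level": 2.0},
    {"variable": "t2d", "kind": "proportion", "column": "t2d"},
    {"variable": "cvd", "kind": "proportion", "column": "cvd"},
    {"variable": "heart_failure", "kind": "proportion", "column": "heart_failure"},
    {"variable": "hypertension", "kind": "proportion", "column": "hypertension"},
    {"variable": "sbp", "kind": "mean_sd", "column": "sbp"},
    {"variable": "dbp", "kind": "mean_sd", "column": "dbp"},
    {"variable": "bmi", "kind": "mean_sd", "column": "bmi"},
    {"variable": "weight", "kind": "mean_sd", "column": "weight"},
    {"variable": "egfr", "kind": "mean_sd", "column": "egfr"},
    {"variable": "acr", "kind": "median_iqr", "column": "acr"},
    {"variable": "ras_inhibitor", "kind": "proportion", "column": "ras_current"},
    {"variable": "acei", "kind": "proportion", "column": "rx_acei"},
    {"variable": "arb", "kind": "proportion", "column": "rx_arb"},
    {"variable": "diuretic", "kind": "proportion", "column": "rx_diuretic"},
    {"variable": "statin", "kind": "proportion", "column": "rx_statin"},
    {"variable": "sglt2i", "kind": "proportion", "column": "rx_sglt2i"},
]
_TRIAL_SPECIFIC_SPECS = {
    "CREDENCE": [
        {"variable": "hba1c", "kind": "mean_sd", "column": "hba1c"},
        {"variable": "egfr_15_30", "kind": "proportion", "column": "egfr", "band": [15, 30]},
        {"variable": "egfr_30_45", "kind": "proportion", "column": "egfr", "band": [30, 45]},
        {"variable": "egfr_45_60", "kind": "proportion", "column": "egfr", "band": [45, 60]},
        {"variable": "egfr_60_90", "kind": "proportion", "column": "egfr", "band": [60, 90]},
        {"variable": "egfr_ge90", "kind": "proportion", "column": "egfr", "band": [90, None]},
        {"variable": "acr_lt3", "kind": "proportion", "column": "acr", "band": [0, 3]},
        {"variable": "acr_3_30", "kind": "proportion", "column": "acr", "band": [3, 30]},
        {"variable": "acr_30_300", "kind": "proportion", "column": "acr", "band": [30, 300]},
        {"variable": "acr_gt300", "kind": "proportion", "column": "acr", "band": [300, None]},
    ],
    "DAPA-CKD": [
        {"variable": "egfr_lt30", "kind": "proportion", "column": "egfr", "band": [0, 30]},
        {"variable": "egfr_30_45", "kind": "proportion", "column": "egfr", "band": [30, 45]},
        {"variable": "egfr_45_60", "kind": "proportion", "column": "egfr", "band": [45, 60]},
        {"variable": "egfr_ge60", "kind": "proportion", "column": "egfr", "band": [60, None]},
        {"variable": "acr_gt113", "kind": "proportion", "column": "acr", "band": [113, None]},
    ],
    "EMPA-KIDNEY": [
        {"variable": "egfr_lt30", "kind": "proportion", "column": "egfr", "band": [0, 30]},
        {"variable": "egfr_30_45", "kind": "proportion", "column": "egfr", "band": [30, 45]},
        {"variable": "egfr_ge45", "kind": "proportion", "column": "egfr", "band": [45, None]},
        {"variable": "acr_lt3", "kind": "proportion", "column": "acr", "band": [0, 3]},
        {"variable": "acr_3_30", "kind": "proportion", "column": "acr", "band": [3, 30]},
        {"variable": "acr_gt30", "kind": "proportion", "column": "acr", "band": [30, None]},
    ],
}


def variable_specs_for(trial: str) -> list[dict]:
    return _COMMON_SPECS + _TRIAL_SPECIFIC_SPECS.get(trial, [])


def build_model_table(profiles: pd.DataFrame, eligible: pd.Series) -> pd.DataFrame:
    """Covariate table for the pre-specified eligibility model."""
    df = pd.DataFrame({
        "age": profiles["age"],
        "sex": profiles["sex"],
        "ethnicity": profiles["ethnicity"],
        "imd_quintile": profiles["imd_quintile"].astype(int),
        "bmi": profiles["bmi"],
        "t2d": profiles["t2d"].astype(float),
        "cvd": profiles["cvd"].astype(float),
        "heart_failure": profiles["heart_failure"].astype(float),
        "hypertension": profiles["hypertension"].astype(float),
        "cmms": profiles["cmms"],
        "statin": profiles["rx_statin"].astype(float),
        "diuretic": profiles["rx_diuretic"].astype(float),
    }, index=profiles.index)
    df["eligible"] = eligible.reindex(profiles.index).astype(float)
    return df


def pooled_models(profiles: pd.DataFrame, audits: dict[str, pd.DataFrame],
                  m: int = 5, iterations: int = 5, seed: int = 0) -> dict:
    """Impute missing model covariates once, then fit and pool per trial.

    Only numeric covariates enter the chained equations (categoricals are
    resolved upstream by the missing-ethnicity-to-White and practice-IMD
    conventions); the eligibility outcome is computed before imputation and
    never imputed.
    """
    numeric = pd.DataFrame({
        "age": profiles["age"],
        "female": (profiles["sex"] == "female").astype(float),
        "bmi": profiles["bmi"],
        "cmms": profiles["cmms"],
        "t2d": profiles["t2d"].astype(float),
        "cvd": profiles["cvd"].astype(float),
        "heart_failure": profiles["heart_failure"].astype(float),
        "hypertension": profiles["hypertension"].astype(float),
        "statin": profiles["rx_statin"].astype(float),
        "diuretic": profiles["rx_diuretic"].astype(float),
    }, index=profiles.index)
    imp = mice_impute(numeric, m=m, iterations=iterations, seed=seed)
    out = {}
    for trial, audit in audits.items():
        eligible = audit.set_index("patient_id")["eligible"]
        if eligible.reindex(profiles.index).nunique() < 2:
            logger.warning("pooled_models: outcome has no variation for %s; model skipped", trial)
            continue
        fits = []
        for completed in imp.completed_tables:
            table = build_model_table(profiles, eligible)
            table["bmi"] = completed["bmi"]
            table["bmi_category"] = bmi_category(table["bmi"])
            fits.append(fit_eligibility_model(table, trial=trial))
        out[trial] = pool_rubin(fits, m=imp.m)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under config.output_dir.

    Returns the in-memory bundle: profiles, register, audits, rates, reasons,
    comparisons, pooled models and the manifest.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "package_version": __version__,
                      "index_date": config.index_date, "counts": {}}
    counts = manifest["counts"]

    if config.synthetic is not None:
        gen_kwargs = dict(config.synthetic)
        gen_kwargs.setdefault("seed", config.seed)
        gen_kwargs.setdefault("index_date", config.index_date)
        gcfg = GeneratorConfig(**gen_kwargs)
        patients, observations, codes, prescriptions, ground_truth = \
            generate_population(gcfg)
        if config.apply_missingness:
            observations, patients = inject_missingness(observations, patients, gcfg)
        write_tables(os.path.join(config.output_dir, "tables"),
                     patients, observations, codes, prescriptions, ground_truth)
    else:
        from .synthetic import read_tables
        patients, observations, codes, prescriptions, ground_truth = \
            read_tables(config.input_dir)

    tables = {"patients": patients, "observations": observations,
              "codes": codes, "prescriptions": prescriptions}
    report = validate_inputs(tables, index_date=config.index_date)
    report.to_csv(os.path.join(config.output_dir, "validation_report.csv"), index=False)
    hard = report[report["level"] == "hard"]
    if len(hard):
        raise DataError(f"input validation failed with {len(hard)} hard findings "
                        f"(see validation_report.csv); first: {hard.iloc[0]['message']}")

    counts["n_patients"] = len(patients)
    observations = observations[observations["date"] <= pd.Timestamp(config.index_date)]
    observations = clean_observations(observations)
    counts["n_observations_clean"] = len(observations)

    register = build_ckd_register(patients, observations, codes,
                                  config.index_date, prescriptions)
    profiles_all = build_profiles(patients, observations, codes,
                                  prescriptions, config.index_date)
    adults = profiles_all["age"] >= 18
    counts["n_adults"] = int(adults.sum())
    ckd_ids = register.loc[register["is_ckd"], "patient_id"]
    profiles = profiles_all.loc[profiles_all["patient_id"].isin(ckd_ids) & adults]
    counts["n_ckd"] = len(profiles)
    register.to_csv(os.path.join(config.output_dir, "ckd_register.csv"), index=False)
    profiles.to_csv(os.path.join(config.output_dir, "ckd_profiles.csv"), index=False)

    specs = load_all_trial_specs(config.trials)
    audits, reasons, crosstabs = {}, [], []
    for trial, spec in specs.items():
        audit = assess_cohort(profiles, spec)
        audit = attribute_primary_reasons(audit, profiles, spec)
        audits[trial] = audit
        counts[f"eligible_{trial}"] = int(audit["eligible"].sum())
        flat = audit.copy()
        for col in ("failed_inclusion", "met_exclusion", "missing_required"):
            flat[col] = flat[col].map(";".join)
        flat.to_csv(os.path.join(config.output_dir,
                                 f"audit_{trial.replace('-', '_').lower()}.csv"),
                    index=False)
        reasons.append(reason_table(audit))
        crosstabs.append(ras_albuminuria_crosstab(audit, profiles, spec))

    t2d_series = profiles.set_index("patient_id")["t2d"]
    rates = eligibility_rates(audits, t2d_series)
    rates.to_csv(os.path.join(config.output_dir, "eligibility_rates.csv"), index=False)
    pd.concat(reasons, ignore_index=True).to_csv(
        os.path.join(config.output_dir, "ineligibility_reasons.csv"), index=False)
    pd.concat(crosstabs, ignore_index=True).to_csv(
        os.path.join(config.output_dir, "no_ras_albuminuria_crosstab.csv"), index=False)

    # complete-case sensitivity rerun of the rates
    cc_profiles = complete_case_filter(profiles, "cc_outcome_labs")
    counts["n_ckd_complete_case"] = len(cc_profiles)
    cc_audits = {t: assess_cohort(cc_profiles, s) for t, s in specs.items()}
    cc_rates = eligibility_rates(cc_audits, t2d_series)
    cc_rates.to_csv(os.path.join(config.output_dir,
                                 "eligibility_rates_complete_case.csv"), index=False)

    # baseline comparison of the eligible cohorts with the published trial arms
    arm_summaries = load_trial_arm_summaries()
    comparisons = []
    for trial, audit in audits.items():
        eligible_ids = audit.loc[audit["eligible"], "patient_id"]
        cohort = profiles.loc[profiles["patient_id"].isin(eligible_ids)]
        if cohort.empty:
            continue
        summary = summarize_cohort(cohort, variable_specs_for(trial))
        arm = arm_summaries[arm_summaries["trial"] == trial]
        comp = compare_to_trial(summary, arm.drop(columns=["trial"]))
        comp["trial"] = trial
        comparisons.append(comp)
    if comparisons:
        pd.concat(comparisons, ignore_index=True).to_csv(
            os.path.join(config.output_dir, "trial_comparison_stdiffs.csv"), index=False)

    models = {}
    if config.fit_models and len(profiles):
        models = pooled_models(profiles, audits, m=config.imputation_m,
                               iterations=config.imputation_iterations,
                               seed=config.seed)
        for trial, pooled in models.items():
            out = pooled.table.copy()
            out.to_csv(os.path.join(
                config.output_dir,
                f"model_{trial.replace('-', '_').lower()}.csv"))

    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {"profiles": profiles, "register": register, "audits": audits,
            "rates": rates, "cc_rates": cc_rates, "models": models,
            "manifest": manifest, "ground_truth": ground_truth}
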