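"""Missing-data handling and eligibility modelling.

Missing clinical measures are imputed by chained equations (predictive mean
matching, m = 5 completed datasets by default), the pre-specified logistic
eligibility model is fitted to each completed dataset, and estimates are
pooled by Rubin's rules:

    pooled estimate  qbar = mean(q_i)
    within variance  W    = mean(se_i^2)
    between variance B    = var(q_i, ddof=1)
    total variance   T    = W + (1 + 1/m) * B
    df (Rubin)            = (m - 1) * (1 + W / ((1 + 1/m) B))^2   (inf if B = 0)

The eligibility outcome itself is never imputed: eligibility is determined
before imputation under the missing-lab-means-ineligible rule.

Chained-equation sweeps are delegated to statsmodels' MICEData (predictive
mean matching for every imputed variable; binary columns are imputed from
observed 0/1 donors, which keeps them binary).  MICEData draws from numpy's
global random state, so reproducibility is provided by seeding that state at
the start of each call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.imputation.mice import MICEData

from .errors import ConfigurationError, ContractError, DataError, ImputationError

BMI_CATEGORIES = ("underweight", "normal", "overweight",
                  "obese_1", "obese_2", "obese_3")

#: covariates of the pre-specified eligibility model
MODEL_TERMS = ("age", "sex", "ethnicity", "imd_quintile", "bmi_category",
               "t2d", "cvd", "heart_failure", "hypertension", "cmms",
               "statin", "diuretic")


def bmi_category(bmi) -> pd.Series:
    """WHO-style six-category body-mass-index classification."""
    bins = [-np.inf, 18.5, 25, 30, 35, 40, np.inf]
    return pd.cut(pd.Series(bmi), bins=bins, right=False,
                  labels=BMI_CATEGORIES).astype(object)


@dataclass
class ImputationSet:
    m: int
    completed_tables: list
    method_per_variable: dict
    seed: int
    iterations: int


def mice_impute(profile_table: pd.DataFrame,
                method_per_variable: dict | None = None,
                m: int = 5, iterations: int = 10, seed: int = 0) -> ImputationSet:
    """Multiple imputation of missing cells by chained equations.

    All columns must be numeric (binary flags as 0/1); categorical model terms
    such as ethnicity are resolved before imputation, mirroring the
    missing-ethnicity-to-White and practice-IMD conventions.  Observed cells
    are preserved bit-for-bit in every completed table.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    table = profile_table.copy()
    non_numeric = [c for c in table.columns if not np.issubdtype(
        np.asarray(table[c]).dtype, np.number)]
    if non_numeric:
        raise ConfigurationError(
            f"imputation table must be numeric; offending columns: {non_numeric}")
    fully_missing = [c for c in table.columns if table[c].isna().all()]
    if fully_missing:
        raise ImputationError(
            f"cannot impute variables with 100% missingness: {fully_missing}")
    method_per_variable = dict(method_per_variable or {})
    bad = {v: meth for v, meth in method_per_variable.items() if meth != "pmm"}
    if bad:
        raise ConfigurationError(f"unsupported imputation methods: {bad}")

    if not table.isna().any().any():
        return ImputationSet(m, [table.copy() for _ in range(m)],
                             method_per_variable, seed, iterations)

    np.random.seed(seed % (2 ** 32))
    completed = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = MICEData(table.reset_index(drop=True))
        for _ in range(m):
            md.update_all(iterations)
            out = md.data.copy()
            out.index = table.index
            completed.append(out)

    observed = ~table.isna()
    for out in completed:  # contract: observed cells unchanged
        assert out.where(observed).equals(table.where(observed))
    return ImputationSet(m, completed, method_per_variable, seed, iterations)


@dataclass
class ModelFit:
    outcome: str
    coefficients: dict
    standard_errors: dict
    n: int
    converged: bool = True
    separation_flag: bool = False


MODEL_FORMULA = (
    "{outcome} ~ age + C(sex, Treatment('male')) + C(ethnicity, Treatment('White'))"
    " + C(imd_quintile, Treatment(5)) + C(bmi_category, Treatment('normal'))"
    "{t2d_term} + cvd + heart_failure + hypertension + cmms + statin + diuretic"
)


def fit_eligibility_model(completed_table: pd.DataFrame, trial: str | None = None,
                          outcome: str = "eligible",
                          formula: str | None = None) -> ModelFit:
    """Maximum-likelihood logistic fit of the pre-specified eligibility model.

    Reference levels: male sex, White ethnicity, IMD quintile 5 (least
    deprived), normal weight.  For CREDENCE the T2D term is dropped and the
    model is fitted within the CKD-T2D cohort (its criteria admit no non-T2D
    patients).  Quasi-separation is flagged, not silently regularised.
    A custom ``formula`` may be supplied for reduced models (e.g. validation
    against closed-form odds ratios).
    """
    df = completed_table.copy()
    if "bmi_category" not in df.columns and "bmi" in df.columns:
        df["bmi_category"] = bmi_category(df["bmi"])
    credence_like = trial == "CREDENCE"
    if credence_like:
        df = df[df["t2d"].astype(bool)]
    y = df[outcome].astype(float)
    if y.nunique() < 2:
        raise DataError(f"outcome {outcome!r} has no variation")
    if formula is None:
        formula = MODEL_FORMULA.format(outcome=outcome,
                                       t2d_term="" if credence_like else " + t2d")
    for col in ("t2d", "cvd", "heart_failure", "hypertension", "statin",
                "diuretic", outcome):
        if col in df.columns:
            df[col] = df[col].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(formula, data=df, family=sm.families.Binomial())
        res = model.fit()
    params = res.params
    bse = res.bse
    separation = bool(np.any(np.abs(params) > 15) or np.any(bse > 50)
                      or np.any(~np.isfinite(bse)))
    return ModelFit(
        outcome=outcome,
        coefficients=dict(params),
        standard_errors=dict(bse),
        n=int(res.nobs),
        converged=bool(res.converged),
        separation_flag=separation,
    )


@dataclass
class PooledModelFit:
    m: int
    table: pd.DataFrame = field(repr=False)

    def __getitem__(self, term):
        return self.table.loc[term]


def pool_rubin(fits: list[ModelFit], m: int | None = None) -> PooledModelFit:
    """Combine per-imputation logistic fits by Rubin's rules.

    Returns a per-term table with the pooled log-odds estimate, within/between
    /total variances, Rubin degrees of freedom, odds ratio, 95% CI and
    two-sided p-value.
    """
    if not fits:
        raise ContractError("no fits to pool")
    m = m if m is not None else len(fits)
    terms = list(fits[0].coefficients)
    for f in fits[1:]:
        if list(f.coefficients) != terms:
            raise ContractError("mismatched term sets across imputations")
    est = np.array([[f.coefficients[t] for t in terms] for f in fits])
    ses = np.array([[f.standard_errors[t] for t in terms] for f in fits])
    qbar = est.mean(axis=0)
    within = (ses ** 2).mean(axis=0)
    between = est.var(axis=0, ddof=1) if len(fits) > 1 else np.zeros(len(terms))
    total = within + (1.0 + 1.0 / m) * between
    df = np.full(len(terms), np.inf)
    pos = between > 0
    df[pos] = (m - 1) * (1.0 + within[pos] / ((1.0 + 1.0 / m) * between[pos])) ** 2
    se_t = np.sqrt(total)
    tcrit = np.where(np.isinf(df), st.norm.ppf(0.975), st.t.ppf(0.975, df))
    tstat = np.divide(qbar, se_t, out=np.zeros_like(qbar), where=se_t > 0)
    pvals = np.where(np.isinf(df), 2 * st.norm.sf(np.abs(tstat)),
                     2 * st.t.sf(np.abs(tstat), df))
    with np.errstate(over="ignore"):  # huge SEs from flagged fits give inf CIs
        table = pd.DataFrame({
            "estimate": qbar, "within_var": within, "between_var": between,
            "total_var": total, "se": se_t, "df": df,
            "or": np.exp(qbar),
            "ci_lo": np.exp(qbar - tcrit * se_t),
            "ci_hi": np.exp(qbar + tcrit * se_t),
            "p": pvals,
        }, index=pd.Index(terms, name="term"))
    return PooledModelFit(m=m, table=table)


CC_DEFINITIONS = ("cc_outcome_labs", "cc_model_vars", "cc_both")


def complete_case_filter(profiles: pd.DataFrame, definition: str) -> pd.DataFrame:
    """Complete-case sensitivity filters.

    * ``cc_outcome_labs`` - patients with both a current eGFR and a current
      urine ACR (recorded within the 2-year recency window);
    * ``cc_model_vars``   - patients with no missing eligibility-model
      covariate;
    * ``cc_both``         - the intersection.
    """
    if definition not in CC_DEFINITIONS:
        raise ConfigurationError(f"unknown complete-case definition {definition!r}")
    keep = pd.Series(True, index=profiles.index)
    if definition in ("cc_outcome_labs", "cc_both"):
        keep &= profiles["egfr"].notna() & profiles["acr"].notna()
    if definition in ("cc_model_vars", "cc_both"):
        cols = [c for c in ("age", "sex", "ethnicity", "imd_quintile", "bmi",
                            "t2d", "cvd", "heart_failure", "hypertension",
                            "cmms", "statin", "diuretic")
                if c in profiles.columns]
        # current-prescription flags may be stored with an rx_ prefix
        for flag in ("statin", "diuretic"):
            if flag not in profiles.columns and f"rx_{flag}" in profiles.columns:
                cols.append(f"rx_{flag}")
        keep &= profiles[cols].notna().all(axis=1)
    return profiles.loc[keep]
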