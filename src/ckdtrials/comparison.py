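"""Baseline-table summaries and standardized differences.

Cohort characteristics are summarized trial-style (mean +/- SD, median [IQR],
or frequency/percentage) and compared with published trial-arm summaries via
standardized differences:

    means:       d = |m1 - m2| / sqrt((s1^2 + s2^2) / 2)
    proportions: d = |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)

Differences above 0.1 are flagged as meaningful.  No standardized difference
is defined for median [IQR] variables; they are reported without one.

Quantiles use the linear-interpolation convention (numpy default).
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

FLAG_THRESHOLD = 0.1


def std_diff_means(m1, s1, m2, s2) -> float:
    """Standardized difference between two means (symmetric, non-negative)."""
    if s1 <= 0 or s2 <= 0:
        raise DomainError("standard deviations must be positive")
    return abs(m1 - m2) / math.sqrt((s1 * s1 + s2 * s2) / 2.0)


def std_diff_proportions(p1, p2) -> float:
    """Standardized difference between two proportions.

    Boundary guard: when both proportions are 0 or 1 the pooled variance is
    zero; the difference is defined as 0 when they are equal and infinity
    otherwise (a degenerate comparison that callers should treat as
    non-informative).
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise DomainError("proportions must lie in [0, 1]")
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    if pooled == 0.0:
        return 0.0 if p1 == p2 else math.inf
    return abs(p1 - p2) / math.sqrt(pooled)


def summarize_cohort(profiles: pd.DataFrame, variable_specs: list[dict]) -> pd.DataFrame:
    """Trial-style baseline summary of a cohort.

    Each variable spec names the summary ``kind`` and the profile ``column``;
    proportions may target a boolean column directly, a half-open value
    ``band`` [lo, hi) of a continuous column, or a categorical ``level``.
    Missing values are excluded variable-wise, with the non-missing n reported;
    band/level percentages are computed over the non-missing values.
    """
    rows = []
    for vs in variable_specs:
        col = profiles[vs["column"]]
        if col.dtype == object:
            vals = col.dropna()
        else:
            vals = pd.to_numeric(col, errors="coerce").dropna()
        row = {"variable": vs["variable"], "kind": vs["kind"], "n": int(len(vals)),
               "mean": np.nan, "sd": np.nan, "proportion": np.nan,
               "median": np.nan, "q1": np.nan, "q3": np.nan}
        if len(vals) == 0:
            rows.append(row)
            continue
        if vs["kind"] == "mean_sd":
            row["mean"] = float(vals.mean())
            row["sd"] = float(vals.std(ddof=1))
        elif vs["kind"] == "proportion":
            if "band" in vs:
                lo, hi = vs["band"]
                hi = np.inf if hi is None else hi
                row["proportion"] = float(((vals >= lo) & (vals < hi)).mean())
            elif "level" in vs:
                row["proportion"] = float((vals == vs["level"]).mean())
            else:
                row["proportion"] = float(vals.astype(bool).mean())
        elif vs["kind"] == "median_iqr":
            q1, med, q3 = np.quantile(vals.to_numpy(dtype=float), [0.25, 0.5, 0.75])
            row.update(median=float(med), q1=float(q1), q3=float(q3))
        else:
            raise DataError(f"unknown summary kind {vs['kind']!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def compare_to_trial(cohort_summary: pd.DataFrame,
                     trial_summary: pd.DataFrame) -> pd.DataFrame:
    """Standardized differences between a cohort summary and a trial arm.

    Rows are paired on ``variable``; a kind mismatch is a data error.  Median
    [IQR] variables are emitted with no standardized difference.  ``flagged``
    is evaluated on the unrounded difference; ``d`` is also reported rounded
    to two decimals as printed in trial-comparison tables.
    """
    merged = cohort_summary.merge(trial_summary, on="variable",
                                  suffixes=("_cohort", "_trial"))
    rows = []
    for _, r in merged.iterrows():
        if r["kind_cohort"] != r["kind_trial"]:
            raise DataError(f"summary kind mismatch for variable {r['variable']!r}")
        kind = r["kind_cohort"]
        if kind == "mean_sd":
            d = std_diff_means(r["mean_cohort"], r["sd_cohort"],
                               r["mean_trial"], r["sd_trial"])
            cohort_value, trial_value = r["mean_cohort"], r["mean_trial"]
        elif kind == "proportion":
            d = std_diff_proportions(r["proportion_cohort"], r["proportion_trial"])
            cohort_value, trial_value = r["proportion_cohort"], r["proportion_trial"]
        else:  # median_iqr: no standardized difference defined
            d = np.nan
            cohort_value, trial_value = r["median_cohort"], r["median_trial"]
        rows.append({
            "trial": r.get("trial", None), "variable": r["variable"], "kind": kind,
            "cohort_value": cohort_value, "trial_value": trial_value,
            "d": d, "d_2dp": np.nan if pd.isna(d) else round(d, 2),
            "flagged": bool(d > FLAG_THRESHOLD) if not pd.isna(d) else False,
        })
    return pd.DataFrame(rows)


def load_trial_arm_summaries() -> pd.DataFrame:
    """Published trial intervention-arm/trial-cohort baseline summaries.

    A curated transcription of published trial baseline tables; proportions
    are stored as fractions.
    """
    ref = resources.files("ckdtrials.data").joinpath("trial_arm_summaries.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


def load_printed_stdiff_checks() -> pd.DataFrame:
    """Transcribed (trial-arm, eligible-cohort, printed standardized difference)
    triples used to validate the standardized-difference formulas."""
    ref = resources.files("ckdtrials.data").joinpath("printed_stdiff_checks.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


def recompute_stdiff_row(row: pd.Series) -> float:
    """Recompute one transcribed standardized-difference row."""
    if row["kind"] == "mean_sd":
        return std_diff_means(row["m1"], row["s1"], row["m2"], row["s2"])
    return std_diff_proportions(row["p1"], row["p2"])
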