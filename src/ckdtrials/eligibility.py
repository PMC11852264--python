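"""Trial eligibility engine for CREDENCE, DAPA-CKD and EMPA-KIDNEY.

Trial specifications are data, not code: each trial ships as a YAML file of
criterion records (identifier, kind, bounds with open/closed flags, the
ineligibility reason a failure maps to).  The engine evaluates every criterion
without short-circuiting so the audit trail is complete, records missing
required laboratory values (a missing lab always means ineligible), and
attributes a primary ineligibility reason by a fixed hierarchy:

    no RAS inhibitor > albuminuria (below threshold, else not assessed)
    > eGFR (out of range, else not assessed) > other inclusion failures
    (age, HbA1c, no T2D) > exclusion criteria.

Unit conversions used when materializing thresholds from trial protocols
(urine ACR mg/g -> mg/mmol; HbA1c NGSP % -> IFCC mmol/mol) are provided here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ContractError, DataError, DomainError
from .vocab import REASON_ORDER, TRIALS

logger = logging.getLogger(__name__)

CREATININE_MOLAR_MASS = 113.12  # g/mol
_TRIAL_FILES = {
    "CREDENCE": "credence.yaml",
    "DAPA-CKD": "dapa_ckd.yaml",
    "EMPA-KIDNEY": "empa_kidney.yaml",
}
_CRITERION_KINDS = frozenset({
    "min_age", "t2d", "lab_range", "current_rx_any",
    "egfr_acr_groups", "code_any", "combined_rx", "t2d_ascvd_egfr",
})


def convert_acr_mg_per_g_to_mg_per_mmol(x):
    """Urine ACR from mg/g (trial protocols) to mg/mmol (UK reporting).

    1 mmol creatinine = 113.12 mg, so x mg/g = x * 113.12/1000 mg/mmol
    (equivalently x / 8.84).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise DomainError("ACR cannot be negative")
    out = arr * CREATININE_MOLAR_MASS / 1000.0
    return out if out.ndim else float(out)


def convert_hba1c_ngsp_to_ifcc(pct):
    """HbA1c from NGSP % to IFCC mmol/mol via the master equation.

    IFCC = (NGSP% - 2.15) * 10.929
    """
    arr = np.asarray(pct, dtype=float)
    if np.any(arr <= 2.15):
        raise DomainError("NGSP HbA1c must exceed 2.15%")
    out = (arr - 2.15) * 10.929
    return out if out.ndim else float(out)


@dataclass
class Criterion:
    id: str
    description: str
    kind: str
    params: dict = field(default_factory=dict)
    reason_fail: str = "other"
    reason_missing: str | None = None


@dataclass
class TrialSpec:
    name: str
    inclusion: list[Criterion]
    exclusion: list[Criterion]
    not_evaluable: list[dict] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.id for c in self.inclusion] + [c.id for c in self.exclusion]
        if len(ids) != len(set(ids)):
            raise ConfigurationError(f"duplicate criterion ids in spec {self.name}")
        for c in self.inclusion + self.exclusion:
            if c.kind not in _CRITERION_KINDS:
                raise ConfigurationError(
                    f"unknown criterion kind {c.kind!r} (criterion {c.id})")


def _spec_from_dict(raw: dict) -> TrialSpec:
    def crits(items):
        return [Criterion(
            id=it["id"], description=it.get("description", ""), kind=it["kind"],
            params=it.get("params", {}) or {},
            reason_fail=it.get("reason_fail", "other"),
            reason_missing=it.get("reason_missing"),
        ) for it in items or []]
    return TrialSpec(
        name=raw["name"],
        inclusion=crits(raw.get("inclusion")),
        exclusion=crits(raw.get("exclusion")),
        not_evaluable=list(raw.get("not_evaluable") or []),
    )


def load_trial_spec(trial: str) -> TrialSpec:
    """Load a shipped trial spec by name, or any spec from a YAML path."""
    if trial in _TRIAL_FILES:
        ref = resources.files("ckdtrials.data.trials").joinpath(_TRIAL_FILES[trial])
        with ref.open() as fh:
            return _spec_from_dict(yaml.safe_load(fh))
    with open(trial) as fh:
        return _spec_from_dict(yaml.safe_load(fh))


def save_trial_spec(spec: TrialSpec, path) -> None:
    raw = {
        "name": spec.name,
        "inclusion": [asdict(c) for c in spec.inclusion],
        "exclusion": [asdict(c) for c in spec.exclusion],
        "not_evaluable": spec.not_evaluable,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def load_all_trial_specs(trials=TRIALS) -> dict[str, TrialSpec]:
    return {t: load_trial_spec(t) for t in trials}


# ---------------------------------------------------------------------------
# criterion evaluation
# ---------------------------------------------------------------------------

def _range_mask(values: np.ndarray, lo, hi, lo_incl, hi_incl) -> np.ndarray:
    above = values >= lo if lo_incl else values > lo
    below = values <= hi if hi_incl else values < hi
    return above & below


def _eval_inclusion(c: Criterion, prof: pd.DataFrame):
    """Return (ok, missing, missing_concept) boolean arrays for one criterion."""
    n = len(prof)
    zeros = np.zeros(n, dtype=bool)
    if c.kind == "min_age":
        return (prof["age"].to_numpy() >= c.params["min"], zeros, None)
    if c.kind == "t2d":
        return (prof["t2d"].to_numpy(), zeros, None)
    if c.kind == "current_rx_any":
        ok = zeros.copy()
        for cls in c.params["classes"]:
            ok |= prof["rx_" + cls.lower()].to_numpy()
        return (ok, zeros, None)
    if c.kind == "lab_range":
        concept = c.params["concept"]
        values = prof[concept].to_numpy(dtype=float)
        missing = np.isnan(values)
        ok = np.where(missing, False, _range_mask(
            values, c.params["lo"], c.params["hi"],
            c.params.get("lo_incl", True), c.params.get("hi_incl", True)))
        return (ok, missing, concept)
    if c.kind == "egfr_acr_groups":
        p = c.params
        egfr = prof["egfr"].to_numpy(dtype=float)
        acr = prof["acr"].to_numpy(dtype=float)
        pcr = prof["pcr"].to_numpy(dtype=float)
        egfr_missing = np.isnan(egfr)
        low_arm = _range_mask(egfr, p["egfr_low_lo"], p["egfr_low_hi"], True, False)
        high_band = _range_mask(egfr, p["egfr_high_lo"], p["egfr_high_hi"], True, False)
        prot = (acr >= p["acr_min"]) | (pcr >= p["pcr_min"])
        ok = np.where(egfr_missing, False, low_arm | (high_band & prot))
        # high-eGFR band with no albuminuria assessment at all: missing lab
        prot_unassessed = np.isnan(acr) & np.isnan(pcr)
        missing = egfr_missing | (high_band & ~low_arm & prot_unassessed & ~egfr_missing)
        return (ok, missing, "egfr")
    raise ConfigurationError(f"criterion kind {c.kind!r} is not an inclusion kind")


def _eval_exclusion(c: Criterion, prof: pd.DataFrame) -> np.ndarray:
    """Return a boolean array: exclusion met.  Absent evidence means not met."""
    n = len(prof)
    if c.kind == "code_any":
        met = np.zeros(n, dtype=bool)
        for flag in c.params["flags"]:
            met |= prof[flag].to_numpy()
        return met
    if c.kind == "combined_rx":
        met = np.ones(n, dtype=bool)
        for cls in c.params["classes"]:
            met &= prof["rx_" + cls.lower()].to_numpy()
        return met
    if c.kind == "t2d_ascvd_egfr":
        egfr = prof["egfr"].to_numpy(dtype=float)
        high = np.where(np.isnan(egfr), False, egfr > c.params["egfr_gt"])
        return prof["t2d"].to_numpy() & prof["ascvd"].to_numpy() & high
    raise ConfigurationError(f"criterion kind {c.kind!r} is not an exclusion kind")


@dataclass
class EligibilityResult:
    patient_id: object
    trial: str
    eligible: bool
    failed_inclusion: list = field(default_factory=list)
    met_exclusion: list = field(default_factory=list)
    missing_required: list = field(default_factory=list)
    primary_reason: str | None = None


def assess_cohort(profiles: pd.DataFrame, spec: TrialSpec) -> pd.DataFrame:
    """Assess every profile against one trial spec (no short-circuiting).

    Returns one row per patient with the eligibility verdict, the complete
    lists of failed inclusion criteria and met exclusion criteria, and the
    required lab concepts that were missing.  A missing required lab always
    yields ineligible.
    """
    n = len(profiles)
    all_ok = np.ones(n, dtype=bool)
    failed: list[list] = [[] for _ in range(n)]
    met: list[list] = [[] for _ in range(n)]
    missing_req: list[list] = [[] for _ in range(n)]

    for c in spec.inclusion:
        ok, missing, concept = _eval_inclusion(c, profiles)
        all_ok &= ok
        for i in np.flatnonzero(~ok & ~missing):
            failed[i].append(c.id)
        if concept is not None:
            if c.kind == "egfr_acr_groups":
                # eGFR present but albuminuria unassessed -> the missing lab is ACR
                egfr_present = ~np.isnan(profiles["egfr"].to_numpy(dtype=float))
                names = np.where(egfr_present, "acr", "egfr")
                for i in np.flatnonzero(missing):
                    missing_req[i].append(names[i])
            else:
                for i in np.flatnonzero(missing):
                    missing_req[i].append(concept)

    any_excl = np.zeros(n, dtype=bool)
    for c in spec.exclusion:
        m = _eval_exclusion(c, profiles)
        any_excl |= m
        for i in np.flatnonzero(m):
            met[i].append(c.id)

    eligible = all_ok & ~any_excl
    return pd.DataFrame({
        "patient_id": profiles["patient_id"].to_numpy(),
        "trial": spec.name,
        "eligible": eligible,
        "failed_inclusion": failed,
        "met_exclusion": met,
        "missing_required": missing_req,
        "primary_reason": [None] * n,
    })


def assess(profile: pd.Series, spec: TrialSpec) -> EligibilityResult:
    """Assess a single resolved profile against one trial spec."""
    row = assess_cohort(pd.DataFrame([profile]), spec).iloc[0]
    return EligibilityResult(
        patient_id=row["patient_id"], trial=row["trial"],
        eligible=bool(row["eligible"]),
        failed_inclusion=list(row["failed_inclusion"]),
        met_exclusion=list(row["met_exclusion"]),
        missing_required=list(row["missing_required"]),
    )


# ---------------------------------------------------------------------------
# primary ineligibility reason
# ---------------------------------------------------------------------------

def _empa_group_reason(profile: pd.Series, params: dict) -> str:
    """Refine the EMPA-KIDNEY two-arm eGFR/albuminuria failure into a reason."""
    egfr = profile["egfr"]
    if pd.isna(egfr):
        return "egfr_not_assessed"
    if egfr < params["egfr_low_lo"] or egfr >= params["egfr_high_hi"]:
        return "egfr_out_of_range"
    # in the high band with insufficient albuminuria
    if pd.isna(profile["acr"]) and pd.isna(profile["pcr"]):
        return "albuminuria_not_assessed"
    return "albuminuria_below_threshold"


def attribute_primary_reason(result: EligibilityResult, profile: pd.Series,
                             spec: TrialSpec) -> EligibilityResult:
    """Assign the primary ineligibility reason by the documented hierarchy.

    All failed criteria remain on the result for overlapping-reason
    tabulations; only ``primary_reason`` is set here.
    """
    if result.eligible:
        raise ContractError("attribute_primary_reason called on an eligible result")
    by_id = {c.id: c for c in spec.inclusion}
    reasons: set[str] = set()
    for cid in result.failed_inclusion:
        c = by_id[cid]
        if c.kind == "egfr_acr_groups":
            reasons.add(_empa_group_reason(profile, c.params))
        else:
            reasons.add(c.reason_fail)
    for concept in result.missing_required:
        c = next(ci for ci in spec.inclusion
                 if ci.params.get("concept") == concept or ci.kind == "egfr_acr_groups")
        if c.kind == "egfr_acr_groups":
            reasons.add(_empa_group_reason(profile, c.params))
        else:
            reasons.add(c.reason_missing or c.reason_fail)
    if result.met_exclusion:
        reasons.add("exclusion_criterion")
    result.primary_reason = min(reasons, key=REASON_ORDER.index) if reasons else "other"
    return result


def _empa_group_reason_vector(prof: pd.DataFrame, params: dict) -> np.ndarray:
    """Vectorised version of _empa_group_reason (values only valid on failing rows)."""
    egfr = prof["egfr"].to_numpy(dtype=float)
    acr = prof["acr"].to_numpy(dtype=float)
    pcr = prof["pcr"].to_numpy(dtype=float)
    out = np.where(
        np.isnan(egfr), "egfr_not_assessed",
        np.where((egfr < params["egfr_low_lo"]) | (egfr >= params["egfr_high_hi"]),
                 "egfr_out_of_range",
                 np.where(np.isnan(acr) & np.isnan(pcr),
                          "albuminuria_not_assessed", "albuminuria_below_threshold")))
    return out


def attribute_primary_reasons(audit: pd.DataFrame, profiles: pd.DataFrame,
                              spec: TrialSpec) -> pd.DataFrame:
    """Reason attribution for a whole audit table (vectorised).

    Recomputes the per-criterion masks on the aligned profiles rather than
    re-parsing the audit lists; the result is identical to applying
    attribute_primary_reason row by row.
    """
    prof = profiles.set_index("patient_id") if profiles.index.name != "patient_id" else profiles
    prof = prof.loc[audit["patient_id"]]
    n = len(audit)
    n_reasons = len(REASON_ORDER)
    priority = {r: i for i, r in enumerate(REASON_ORDER)}
    best = np.full(n, priority["other"], dtype=int)

    def improve(mask: np.ndarray, reasons) -> None:
        if np.isscalar(reasons) or isinstance(reasons, str):
            pr = np.full(n, priority[reasons], dtype=int)
        else:
            pr = np.array([priority[r] for r in reasons], dtype=int)
        best[mask] = np.minimum(best[mask], pr[mask])

    for c in spec.inclusion:
        ok, missing, _ = _eval_inclusion(c, prof)
        if c.kind == "egfr_acr_groups":
            refined = _empa_group_reason_vector(prof, c.params)
            improve((~ok).astype(bool), refined)
        else:
            improve(~ok & ~missing, c.reason_fail)
            if missing.any():
                improve(missing, c.reason_missing or c.reason_fail)

    any_excl = np.zeros(n, dtype=bool)
    for c in spec.exclusion:
        any_excl |= _eval_exclusion(c, prof)
    improve(any_excl, "exclusion_criterion")

    eligible = audit["eligible"].to_numpy()
    labels = np.array(REASON_ORDER)[np.minimum(best, n_reasons - 1)]
    audit = audit.copy()
    audit["primary_reason"] = np.where(eligible, None, labels)
    return audit


# ---------------------------------------------------------------------------
# rates and reason tables
# ---------------------------------------------------------------------------

def eligibility_rates(audits: dict[str, pd.DataFrame], t2d: pd.Series) -> pd.DataFrame:
    """Eligibility rate table per trial and stratum with one-decimal percentages.

    ``audits`` maps trial name to its per-patient audit table covering the CKD
    register; ``t2d`` is a boolean Series indexed by patient_id.  CREDENCE is
    reported against the full CKD cohort and the CKD-T2D cohort only, since
    its criteria exclude non-T2D by construction.  Zero-denominator strata are
    flagged in the log and not emitted.
    """
    rows = []
    for trial, audit in audits.items():
        is_t2d = audit["patient_id"].map(t2d).fillna(False).astype(bool).to_numpy()
        strata = {
            "all_CKD": np.ones(len(audit), dtype=bool),
            "CKD_T2D": is_t2d,
            "CKD_no_T2D": ~is_t2d,
        }
        if trial == "CREDENCE":
            strata.pop("CKD_no_T2D")
        for name, mask in strata.items():
            den = int(mask.sum())
            if den == 0:
                logger.warning("eligibility_rates: zero denominator for %s / %s; row not emitted",
                               trial, name)
                continue
            num = int((audit["eligible"].to_numpy() & mask).sum())
            rows.append({
                "trial": trial, "stratum": name, "numerator": num,
                "denominator": den, "percent": round(100.0 * num / den, 1),
            })
    return pd.DataFrame(rows)


def reason_table(audit: pd.DataFrame) -> pd.DataFrame:
    """Primary ineligibility reason counts and percentages among the ineligible."""
    inel = audit[~audit["eligible"]]
    counts = inel["primary_reason"].value_counts()
    total = len(inel)
    return pd.DataFrame({
        "trial": audit["trial"].iloc[0] if len(audit) else None,
        "reason": counts.index,
        "n": counts.to_numpy(),
        "percent_of_ineligible": np.round(100.0 * counts.to_numpy() / total, 1),
    })


def ras_albuminuria_crosstab(audit: pd.DataFrame, profiles: pd.DataFrame,
                             spec: TrialSpec) -> pd.DataFrame:
    """Among patients ineligible for lack of a RAS prescription, tabulate their
    albuminuria status (below threshold / not assessed / meets threshold),
    mirroring the overlapping-reason breakdowns reported alongside rates."""
    prof = profiles.set_index("patient_id") if profiles.index.name != "patient_id" else profiles
    no_ras = audit[(~audit["eligible"]) & (audit["primary_reason"] == "not_on_RAS")]
    acr_crit = next((c for c in spec.inclusion if c.kind in ("lab_range", "egfr_acr_groups")
                     and (c.params.get("concept") == "acr" or c.kind == "egfr_acr_groups")), None)
    sub = prof.loc[no_ras["patient_id"]]
    if acr_crit is None or sub.empty:
        status = np.full(len(sub), "not_applicable")
    elif acr_crit.kind == "egfr_acr_groups":
        ok, _, _ = _eval_inclusion(acr_crit, sub)
        status = np.where(ok, "meets_threshold",
                          _empa_group_reason_vector(sub, acr_crit.params))
    else:
        ok, missing, _ = _eval_inclusion(acr_crit, sub)
        status = np.where(missing, "albuminuria_not_assessed",
                          np.where(ok, "meets_threshold", "albuminuria_below_threshold"))
    counts = pd.Series(status).value_counts()
    total = max(len(no_ras), 1)
    return pd.DataFrame({
        "trial": spec.name,
        "albuminuria_status": counts.index,
        "n": counts.to_numpy(),
        "percent_of_no_RAS": np.round(100.0 * counts.to_numpy() / total, 1),
    })
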