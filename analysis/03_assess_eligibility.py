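#!/usr/bin/env python
"""Assess every CKD patient against the three trials' enrolment criteria.

Writes per-trial audit tables, the eligibility rate table (overall and by T2D
stratum, plus the complete-case sensitivity rerun) and the ineligibility
reason breakdowns under results/analysis.
"""

import argparse

from ckdtrials.eligibility import (assess_cohort, attribute_primary_reasons,
                                   eligibility_rates, load_all_trial_specs,
                                   ras_albuminuria_crosstab, reason_table)
from ckdtrials.imputation import complete_case_filter
from ckdtrials.phenotyping import (build_ckd_register, build_profiles,
                                   clean_observations)
from ckdtrials.synthetic import read_tables

import pandas as pd

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--tables", default="results/analysis/tables")
parser.add_argument("--index-date", default="2022-12-31")
parser.add_argument("--out", default="results/analysis")
args = parser.parse_args()

patients, obs, codes, rx, truth = read_tables(args.tables)
obs = clean_observations(obs)
register = build_ckd_register(patients, obs, codes, args.index_date, rx)
profiles = build_profiles(patients, obs, codes, rx, args.index_date)
profiles = profiles[profiles["patient_id"].isin(
    register.loc[register["is_ckd"], "patient_id"])]

specs = load_all_trial_specs()
audits, reasons, crosstabs = {}, [], []
for trial, spec in specs.items():
    audit = attribute_primary_reasons(assess_cohort(profiles, spec), profiles, spec)
    audits[trial] = audit
    reasons.append(reason_table(audit))
    crosstabs.append(ras_albuminuria_crosstab(audit, profiles, spec))
    flat = audit.copy()
    for col in ("failed_inclusion", "met_exclusion", "missing_required"):
        flat[col] = flat[col].map(";".join)
    flat.to_csv(f"{args.out}/audit_{trial.replace('-', '_').lower()}.csv", index=False)

t2d = profiles.set_index("patient_id")["t2d"]
rates = eligibility_rates(audits, t2d)
rates.to_csv(f"{args.out}/eligibility_rates.csv", index=False)
pd.concat(reasons, ignore_index=True).to_csv(
    f"{args.out}/ineligibility_reasons.csv", index=False)
pd.concat(crosstabs, ignore_index=True).to_csv(
    f"{args.out}/no_ras_albuminuria_crosstab.csv", index=False)

cc = complete_case_filter(profiles, "cc_outcome_labs")
cc_rates = eligibility_rates({t: assess_cohort(cc, s) for t, s in specs.items()}, t2d)
cc_rates.to_csv(f"{args.out}/eligibility_rates_complete_case.csv", index=False)

print("eligibility rates (primary analysis):")
print(rates.to_string(index=False))
print(f"\ncomplete-case CKD population: {len(cc)} of {len(profiles)}")
print(cc_rates[cc_rates["stratum"] == "all_CKD"].to_string(index=False))
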