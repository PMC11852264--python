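#!/usr/bin/env python
"""Model factors associated with trial eligibility.

Imputes missing model covariates by chained equations (m = 5), fits the
pre-specified logistic eligibility model per completed dataset and trial, and
pools by Rubin's rules.  Writes one odds-ratio table per trial under
results/analysis.
"""

import argparse

from ckdtrials.eligibility import assess_cohort, load_all_trial_specs
from ckdtrials.phenotyping import (build_ckd_register, build_profiles,
                                   clean_observations)
from ckdtrials.pipeline import pooled_models
from ckdtrials.synthetic import read_tables

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--tables", default="results/analysis/tables")
parser.add_argument("--index-date", default="2022-12-31")
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--m", type=int, default=5)
parser.add_argument("--out", default="results/analysis")
args = parser.parse_args()

patients, obs, codes, rx, _ = read_tables(args.tables)
obs = clean_observations(obs)
register = build_ckd_register(patients, obs, codes, args.index_date, rx)
profiles = build_profiles(patients, obs, codes, rx, args.index_date)
profiles = profiles[profiles["patient_id"].isin(
    register.loc[register["is_ckd"], "patient_id"])]

audits = {t: assess_cohort(profiles, s)
          for t, s in load_all_trial_specs().items()}
models = pooled_models(profiles, audits, m=args.m, seed=args.seed)

for trial, pooled in models.items():
    path = f"{args.out}/model_{trial.replace('-', '_').lower()}.csv"
    pooled.table.to_csv(path)
    print(f"\n{trial} (n eligible = {int(audits[trial]['eligible'].sum())}; "
          f"pooled over m = {pooled.m}):")
    show = pooled.table[["or", "ci_lo", "ci_hi", "p"]].round(3)
    print(show.to_string())
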