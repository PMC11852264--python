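#!/usr/bin/env python
"""Phenotype the population: clean labs, identify the CKD register, resolve
current profiles at the index date (31 December 2022).

Reads the tables written by 01_generate_cohort.py and writes the CKD register
and per-patient current profiles under results/analysis.
"""

import argparse

from ckdtrials.phenotyping import (build_ckd_register, build_profiles,
                                   clean_observations)
from ckdtrials.synthetic import read_tables

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--tables", default="results/analysis/tables")
parser.add_argument("--index-date", default="2022-12-31")
parser.add_argument("--out", default="results/analysis")
args = parser.parse_args()

patients, obs, codes, rx, truth = read_tables(args.tables)
n_raw = len(obs)
obs = clean_observations(obs)
register = build_ckd_register(patients, obs, codes, args.index_date, rx)
profiles = build_profiles(patients, obs, codes, rx, args.index_date)

register.to_csv(f"{args.out}/ckd_register.csv", index=False)
profiles.to_csv(f"{args.out}/profiles.csv", index=False)

n_ckd = int(register["is_ckd"].sum())
print(f"cleaned observations: {n_raw} -> {len(obs)} rows")
print(f"CKD register: {n_ckd} of {len(register)} patients "
      f"({100 * n_ckd / len(register):.1f}%)")
for basis in ("basis_code", "basis_egfr", "basis_proteinuria"):
    share = register.loc[register["is_ckd"], basis].mean()
    print(f"  route {basis.removeprefix('basis_')}: {100 * share:.1f}% of CKD")
t2d = register.loc[register["is_ckd"], "diabetes_class"].eq("T2D").mean()
print(f"  co-existing T2D: {100 * t2d:.1f}% of CKD")
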