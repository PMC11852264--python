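#!/usr/bin/env python
"""Generate the synthetic primary-care population used by the analysis.

Emits the four EHR-like tables plus the ground-truth table under
results/analysis/tables, with the study conditions as defaults: 7.7% CKD
prevalence, 32.8% of CKD with T2D, planted eligible fractions 0.9/2.2/8.0%
(CREDENCE/DAPA-CKD/EMPA-KIDNEY) and the configured MAR/MNAR missingness.
"""

import argparse

from ckdtrials.synthetic import (GeneratorConfig, generate_population,
                                 inject_missingness, write_tables)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--n", type=int, default=50_000)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", default="results/analysis/tables")
args = parser.parse_args()

cfg = GeneratorConfig(n_patients=args.n, seed=args.seed)
patients, obs, codes, rx, truth = generate_population(cfg)
obs, patients = inject_missingness(obs, patients, cfg)
write_tables(args.out, patients, obs, codes, rx, truth)
cfg.to_yaml(f"{args.out}/generator_config.yaml")

n_ckd = int(truth["is_ckd"].sum())
print(f"generated {args.n} patients -> {args.out}")
print(f"  CKD (planted): {n_ckd} ({100 * n_ckd / args.n:.1f}%)")
print(f"  CKD with T2D:  {100 * truth.loc[truth['is_ckd'], 'has_t2d'].mean():.1f}%")
for trial in ("CREDENCE", "DAPA-CKD", "EMPA-KIDNEY"):
    f = truth.loc[truth["is_ckd"], f"eligible_{trial}"].mean()
    print(f"  planted eligible, {trial}: {100 * f:.1f}% of CKD")
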