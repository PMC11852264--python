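# Methods

This note documents the models, conventions and design choices behind the
package, and what the synthetic-data tests do and do not establish about real
primary-care data.

## Phenotyping conventions

* **Units.** Serum creatinine is stored in µmol/L (UK convention) and divided
  by 88.42 for the mg/dL form of the CKD-EPI 2021 equation; urine ACR/PCR in
  mg/mmol; HbA1c in IFCC mmol/mol.
* **eGFR age.** eGFR is evaluated with the patient's age at the measurement
  date — the value a laboratory would have reported with the result — rather
  than age at the index date.  The difference is at most ~1% over the 2-year
  currency window but keeps historical ascertainment coherent.
* **CKD ontology.** A patient is CKD if any route fires: a coded diagnosis;
  two eGFR < 60 mL/min/1.73 m² from creatinine measurements ≥ 90 days apart;
  or two urine ACR > 3 mg/mmol (or two PCR > 15 mg/mmol) ≥ 90 days apart.
  "Two measurements ≥ 90 days apart" is read as *the existence of at least
  one qualifying pair* (equivalently: the date span of qualifying
  measurements reaches 90 days), not as a consecutive-measurement rule; the
  pairwise brute-force oracle in the tests pins this interpretation down.
  ACR and PCR pairs qualify separately — one ACR plus one PCR do not form a
  pair (different units and assays; the conservative reading).
  Ascertainment uses the **full history**; the 2-year currency window applies
  only to characteristics and eligibility values.
* **Currency.** "Current" clinical measures are the most recent values
  strictly less than 2 years (730 days) old at the index date; ties on the
  recording date are broken deterministically by input order (last record
  wins) with a logged warning.  A current prescription is one issued within
  the last 90 days (inclusive).
* **Diabetes.** T1D if a T1D code is present (precedence over T2D); T2D by
  code, or by two HbA1c ≥ 48 mmol/mol ≥ 90 days apart (the conventional
  diagnostic cut), or optionally by prescriptions from configurable
  glucose-lowering drug classes.  That prescription route is **off by
  default**: none of the modelled drug classes (ACEi, ARB, diuretic, statin,
  SGLT2i) is diabetes-specific, so enabling it by default would
  misclassify.
* **Cleaning.** Values outside shipped plausible ranges (e.g. creatinine
  20–3000 µmol/L) are removed and treated as missing, with per-concept
  removal counts logged.

## Eligibility engine

Trial criteria are data: YAML records with an identifier, a kind
(`min_age`, `t2d`, `lab_range`, `current_rx_any`, `egfr_acr_groups`,
`code_any`, `combined_rx`, `t2d_ascvd_egfr`), bound values with explicit
open/closed flags, and the ineligibility reason a failure maps to.  Boundary
semantics follow the operationalized criterion table verbatim (CREDENCE ACR
strictly > 33.9 but ≤ 565.5; DAPA-CKD ACR ≥ 22.6 and ≤ 565 — the two upper
bounds differ even though both derive from 5000 mg/g, and they are carried
as printed rather than harmonized).  Criteria that cannot be derived from
coded primary-care data are retained in the specs as `not_evaluable` entries
so the audit trail records their existence; unknown or unevaluable exclusion
evidence counts as "exclusion not met".

All criteria are evaluated without short-circuiting so the failed/met lists
are complete; a missing required lab always forces ineligibility.  The
EMPA-KIDNEY eGFR/albuminuria inclusion is a two-arm group: eGFR 20–<45 needs
no albuminuria; eGFR 45–<90 requires ACR ≥ 22.6 mg/mmol **or** PCR ≥ 33.9
mg/mmol (either measure qualifies when both are present).  Primary
ineligibility reasons follow a fixed hierarchy — no RAS inhibitor →
albuminuria below threshold → albuminuria not assessed → eGFR out of range →
eGFR not assessed → age → HbA1c → no T2D → exclusion — while all failed
criteria remain available for overlapping-reason cross-tabulations.  An ACR
above the upper bound maps to the albuminuria-below-threshold reason label
(the label reads as "did not meet the albuminuria criterion"; above-bound
values are rare).

Rates are reported per trial and stratum (all CKD, CKD-T2D, CKD without T2D)
as one-decimal percentages of rounded counts; CREDENCE is reported only
against all-CKD and CKD-T2D because its criteria exclude non-T2D patients by
construction.  Zero-denominator strata are logged and not emitted.

## Standardized differences and summaries

Two-group standardized differences use the standard forms
|m₁−m₂|/√((s₁²+s₂²)/2) and |p₁−p₂|/√((p₁(1−p₁)+p₂(1−p₂))/2); these forms are
validated against ~75 published trial-vs-cohort values, all of which
recompute to the printed two decimals within ±0.01 (the tolerance covers
rounding of the published summary inputs).  Differences > 0.1 are flagged on
the unrounded value.  When both proportions are boundary values (0 or 1) the
pooled variance vanishes; the difference is defined as 0 when equal and
infinity otherwise, and such comparisons should be read as non-informative.
Median [IQR] variables carry no standardized difference.  Quantiles use the
linear-interpolation convention.  Published trial-arm summaries ship as a
curated transcription (`data/trial_arm_summaries.csv`,
`data/printed_stdiff_checks.csv`), clearly marked as transcriptions.

## Missing data and models

Eligibility is determined **before** imputation under the
missing-lab-means-ineligible rule and is never imputed; imputation serves the
covariates of the eligibility models only.  Chained equations run through
statsmodels' MICEData with predictive mean matching for every imputed
variable (binary columns draw observed 0/1 donors, i.e. classification-style
imputations); defaults are m = 5 completed datasets and 10 sweeps, all
configurable.  Categorical conventions are resolved upstream instead of
imputed: missing ethnicity is assigned to White (ethnicity missingness is
treated as not-at-random) and missing IMD quintile falls back to the practice
quintile.  Observed cells are preserved bit-for-bit.  MICEData offers no rng
argument, so reproducibility is provided by seeding numpy's global state per
call.

The pre-specified logistic model regresses trial eligibility on age (years,
linear), sex (ref. male), ethnicity (5 levels, ref. White), IMD quintile
(ref. 5, least deprived), BMI category (six WHO-style classes, ref. normal),
T2D, CVD, heart failure, hypertension, the multimorbidity score (linear), and
current statin and diuretic prescriptions.  For CREDENCE the T2D term is
dropped and the model is fitted within the CKD-T2D cohort.  Fits are plain
maximum likelihood (statsmodels GLM); separation is flagged on the fit, never
silently regularised.  Rubin pooling uses the mean estimate, total variance
T = W + (1 + 1/m)B, and degrees of freedom (m−1)(1 + W/((1+1/m)B))²
(infinite when B = 0, in which case normal quantiles apply); p-values are
two-sided with no multiplicity adjustment.

Complete-case definitions: `cc_outcome_labs` (current eGFR and ACR),
`cc_model_vars` (no missing model covariate), `cc_both` (intersection);
filters are idempotent and monotone.

## Synthetic-data generator

The generator defines the study conditions.  Defaults: 7.7% CKD prevalence
among adults, 32.8% of CKD with co-existing T2D, planted eligible fractions
0.9% / 2.2% / 8.0% (CREDENCE / DAPA-CKD / EMPA-KIDNEY) among CKD, RAS
inhibitors in 45.1% of CKD, albuminuria assessed in 70% of CKD, index date
31 December 2022.  Per-variable missingness rates and the 8% staleness
fraction are not estimates of any real dataset — no per-variable rates are
published for the emulated setting — and are documented placeholders.

**Eligibility planting.** Within the CKD stratum each trial's eligibility is
Bernoulli with logit b_trial + x'β, where β is the configurable coefficient
map (ground truth for recovery tests) over exactly the model covariates, and
each b_trial is calibrated by root-finding so the expected eligible fraction
over the realized covariates equals the target.  DAPA-CKD and EMPA-KIDNEY
share one uniform latent (so DAPA ⊂ EMPA, requiring target_D ≤ target_E);
CREDENCE uses an independent latent gated on T2D.  Marginally each indicator
is exactly logistic, so the pre-specified model is correctly specified and
its coefficients are recoverable.

**Realizing the pattern.** Each realized (CREDENCE, DAPA, EMPA) pattern maps
to a laboratory/code/prescription recipe drawn inside safe sub-intervals of
the criterion windows (≥ 0.5 units from every threshold, absorbing value
rounding), with creatinine obtained by inverting the CKD-EPI equation at the
measurement-date age.  Trial-discordant patterns use trial-specific
exclusions: ADPKD (excludes DAPA and EMPA but not CREDENCE), lupus nephritis
(DAPA only), the T2D + atherosclerotic CVD + eGFR > 60 exclusion (EMPA
only), kidney transplantation (all three).  Ineligible patients split into
no-RAS, low-albuminuria-on-RAS, proteinuria-with-preserved-eGFR and
coded-exclusion archetypes; T1D codes are planted only among non-T2D
ineligible patients so the classified T2D flag equals the generating
covariate.  On complete data, re-deriving phenotype and eligibility
reproduces the ground truth exactly — a property the tests assert patient by
patient at n = 4 000 and n = 200 000.

Visit cadence is a renewal process (three creatinine visits for CKD patients
spanning ≥ 190 days; lab pairs ≥ 95 days apart), a modelling convenience —
nothing is claimed about real sampling cadence.  All randomness flows from
one seed through named substreams, so identical configurations give
byte-identical tables.

**Missingness injection** operates on the complete tables: MAR gaps for
clinical measures (probability depends only on observed sex), MNAR for
ethnicity (non-White records 2.5× as likely to be missing, renormalised to
the configured overall rate) and optionally value-dependent MNAR for
measures; staleness back-dates a configured fraction of each core lab series
so its latest value falls outside the 2-year window.  Because missing labs
mean ineligible, observed eligibility rates under missingness fall below the
planted complete-data targets, and the complete-case sensitivity raises them
again — the same direction reported for real data.

**What the generator does not emulate:** disease progression and
within-patient trajectories beyond what the eligibility logic needs,
correlated comorbidity structure, real SNOMED coding behaviour (closed
vocabulary only), practice-level clustering, or realistic joint
distributions of labs and demographics.  Passing tests therefore establish
the *correctness of the pipeline's logic and statistics under the stated
assumptions*, not the representativeness of any particular rate for real
primary care.

## Numerical and testing choices

* Threshold conversions: ACR mg/g → mg/mmol via creatinine molar mass 113.12
  g/mol; HbA1c NGSP % → IFCC via (% − 2.15) × 10.929; thresholds rounded to
  one decimal when materialized in specs.
* `generate_lab_series` accepts a zero noise SD (deterministic series);
  negative SDs are configuration errors.
* Logistic parameter recovery is asserted as **aggregate** 95% CI coverage
  ≥ 90% across all model terms and 20 seeded replicates of n = 20 000 CKD
  patients (a per-term 18-of-20 rule would fail ~7.5% of the time per term
  at nominal coverage purely by chance, i.e. almost surely somewhere across
  22 terms).  Replicates use `ckd_prevalence = 1` so the model is fitted on
  20 000 CKD patients — the cohort the model is defined on.
* Problem sizes in the test suite: 4 000 patients for fixture-based checks,
  20 000 for single planted-fraction and recovery replicates, 200 000 for
  the planted-fraction acceptance run; these sizes give binomial/SE
  tolerances that make the checks sharp while the full suite runs in well
  under a minute per acceptance property.

## Known limitations

* The eligibility audit's `not_evaluable` entries record criteria that cannot
  be derived from coded data; like the emulated analysis, eligible counts may
  be overestimated relative to full protocol screening.
* "Maximum tolerated dose of RAS inhibitor" is proxied by any current RAS
  prescription; EMPA-KIDNEY's RAS requirement is applied to all arms as
  operationalized, although a minority of actual trial participants were not
  on RAS inhibitors.
* The generator's single shared coefficient vector across trials is a
  simplification; real eligibility determinants differ by trial.
* PCR-only albuminuria ascertainment is generated sparsely (mild-proteinuria
  archetype); the PCR arm of the EMPA-KIDNEY criterion is exercised by unit
  tests rather than at population scale.
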