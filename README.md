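# ckdtrials

Eligibility emulation of the SGLT2 inhibitor kidney outcome trials —
CREDENCE, DAPA-CKD and EMPA-KIDNEY — in a primary-care chronic kidney
disease (CKD) population.

## The problem

Kidney-outcome trials of SGLT2 inhibitors enrolled participants at high risk
of kidney events: albuminuric, mostly on renin–angiotensin-system (RAS)
inhibitors, often with type 2 diabetes (T2D). How many people with CKD in
routine primary care would actually have qualified?  Answering that from
electronic health records requires four linked steps, each implemented and
tested here:

1. **Phenotyping** (`ckdtrials.phenotyping`) — clean observations against
   plausible ranges; compute eGFR with the race-free CKD-EPI 2021 equation

   `eGFR = 142 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.200 · 0.9938^age · 1.012[female]`

   (Scr in mg/dL; κ = 0.7 F / 0.9 M; α = −0.241 F / −0.302 M); identify CKD
   ontologically (diagnostic code, or two eGFR < 60 mL/min/1.73 m² at least
   90 days apart, or repeated proteinuria: ACR > 3 / PCR > 15 mg/mmol); and
   resolve each patient's *current* profile at an index date (latest values
   within 2 years; prescriptions within 90 days).
2. **Eligibility** (`ckdtrials.eligibility`) — trial criteria are shipped as
   data (YAML), with explicit open/closed bounds (e.g. CREDENCE: eGFR ≥ 30
   and < 90, urine ACR > 33.9 and ≤ 565.5 mg/mmol, HbA1c 47.5–107.7
   mmol/mol).  Every criterion is evaluated without short-circuiting, missing
   required labs force ineligibility, and each ineligible patient gets a
   primary reason by a fixed hierarchy (no RAS inhibitor → albuminuria →
   eGFR → other inclusions → exclusions).
3. **Comparison** (`ckdtrials.comparison`) — trial-style baseline summaries
   and standardized differences, `|m₁−m₂| / √((s₁²+s₂²)/2)` for means and
   `|p₁−p₂| / √((p₁(1−p₁)+p₂(1−p₂))/2)` for proportions, flagged at > 0.1.
4. **Missing-data modelling** (`ckdtrials.imputation`) — chained-equation
   imputation (predictive mean matching, m = 5), pre-specified logistic
   eligibility models (age, sex, ethnicity, IMD quintile, BMI category, T2D,
   CVD, heart failure, hypertension, multimorbidity score, statin, diuretic),
   Rubin's-rules pooling, and complete-case sensitivity filters.

Because the underlying patient records are not publicly available, the
package includes a **synthetic EHR generator** (`ckdtrials.synthetic`) that
emits the four input tables with planted ground truth — CKD status, T2D
status and per-trial eligibility drawn from a configurable logistic model —
such that re-deriving phenotype and eligibility on complete data reproduces
the planted truth exactly, patient by patient.  Every downstream stage is
tested against that oracle.

## Worked example

```bash
python analysis/01_generate_cohort.py --n 30000 --seed 1
python analysis/02_phenotype_ckd.py
python analysis/03_assess_eligibility.py
```

prints (seed 1, n = 30 000):

```
CKD register: 2298 of 30000 patients (7.7%)
  co-existing T2D: 33.0% of CKD

eligibility rates (primary analysis):
      trial    stratum  numerator  denominator  percent
   CREDENCE    all_CKD          8         2298      0.3
   CREDENCE    CKD_T2D          8          759      1.1
   DAPA-CKD    all_CKD         41         2298      1.8
   DAPA-CKD    CKD_T2D         21          759      2.8
   DAPA-CKD CKD_no_T2D         20         1539      1.3
EMPA-KIDNEY    all_CKD        162         2298      7.0
EMPA-KIDNEY    CKD_T2D         82          759     10.8
EMPA-KIDNEY CKD_no_T2D         80         1539      5.2

complete-case CKD population: 1346 of 2298
   CREDENCE all_CKD          8         1346      0.6
   DAPA-CKD all_CKD         41         1346      3.0
EMPA-KIDNEY all_CKD        120         1346      8.9
```

Reading: 7.7% of the synthetic adult population is identified as CKD; under
the configured missingness, 0.3–7.0% of the CKD cohort meets each trial's
criteria (missing labs count as ineligible), every trial is more applicable
to the CKD-T2D stratum than to CKD without T2D, and restricting to patients
with current eGFR and ACR (the complete-case sensitivity) raises every rate.
`analysis/04_compare_with_trials.py` then contrasts each eligible cohort
with the published trial arms (the eligible cohorts are older, less
albuminuric and less often on SGLT2 inhibitors — large standardized
differences), and `analysis/05_model_eligibility.py` fits the pooled
logistic eligibility models (e.g. T2D OR ≈ 1.9 and hypertension OR ≈ 2.4 for
EMPA-KIDNEY eligibility in the run above).

The same pipeline runs from a config file over either a synthetic block or
four existing delimited tables:

```bash
ckdtrials generate --n 5000 --seed 7 --out tables/
ckdtrials assess --tables tables/ --out results/run
```

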