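# Plausible value ranges per observation concept, in the concept's fixed units.
# Values outside [lo, hi] are removed during cleaning and treated as missing.
# Ranges follow common UK primary-care data-cleaning practice.
serum_creatinine: [20, 3000]     # umol/L
urine_acr: [0, 1500]             # mg/mmol
urine_pcr: [0, 3000]             # mg/mmol
hba1c: [15, 200]                 # mmol/mol
sbp: [60, 260]                   # mmHg
dbp: [30, 160]                   # mmHg
bmi: [12, 80]                    # kg/m2
weight: [25, 350]                # kg
smoking_status: [0, 2]           # coded 0/1/2
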