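trial,variable,kind,m1,s1,p1,m2,s2,p2,printed_d
DAPA-CKD,age,mean_sd,61.8,12.1,,73.1,12.7,,0.91
DAPA-CKD,female,proportion,,,0.329,,,0.340,0.02
DAPA-CKD,ethnicity_white,proportion,,,0.522,,,0.789,0.59
DAPA-CKD,ethnicity_asian,proportion,,,0.348,,,0.105,0.61
DAPA-CKD,ethnicity_black,proportion,,,0.048,,,0.049,0.00
DAPA-CKD,ethnicity_other,proportion,,,0.081,,,0.009,0.35
DAPA-CKD,current_smoker,proportion,,,0.132,,,0.100,0.10
DAPA-CKD,t2d,proportion,,,0.676,,,0.698,0.05
DAPA-CKD,cvd,proportion,,,0.378,,,0.547,0.34
DAPA-CKD,heart_failure,proportion,,,0.109,,,0.186,0.22
DAPA-CKD,sbp,mean_sd,136.7,17.5,,138.9,18.6,,0.12
DAPA-CKD,dbp,mean_sd,77.5,10.7,,75.7,11.6,,0.16
DAPA-CKD,bmi,mean_sd,29.4,6.0,,29.9,6.3,,0.08
DAPA-CKD,weight,mean_sd,81.5,20.1,,84.9,20.4,,0.17
DAPA-CKD,egfr,mean_sd,43.2,12.3,,50.6,13.6,,0.57
DAPA-CKD,egfr_lt30,proportion,,,0.136,,,0.075,0.20
DAPA-CKD,egfr_30_45,proportion,,,0.455,,,0.295,0.34
DAPA-CKD,egfr_45_60,proportion,,,0.300,,,0.344,0.09
DAPA-CKD,egfr_ge60,proportion,,,0.109,,,0.286,0.46
DAPA-CKD,acr_gt113,proportion,,,0.487,,,0.209,0.61
DAPA-CKD,ras_inhibitor,proportion,,,0.984,,,1.000,0.18
DAPA-CKD,acei,proportion,,,0.313,,,0.613,0.63
DAPA-CKD,arb,proportion,,,0.671,,,0.396,0.57
DAPA-CKD,diuretic,proportion,,,0.431,,,0.362,0.14
DAPA-CKD,statin,proportion,,,0.648,,,0.753,0.23
DAPA-CKD,sglt2i,proportion,,,1.000,,,0.179,3.03
EMPA-KIDNEY,age,mean_sd,63.9,13.9,,78.0,11.7,,1.10
EMPA-KIDNEY,female,proportion,,,0.332,,,0.490,0.33
EMPA-KIDNEY,ethnicity_white,proportion,,,0.587,,,0.850,0.61
EMPA-KIDNEY,ethnicity_asian,proportion,,,0.361,,,0.060,0.79
EMPA-KIDNEY,ethnicity_black,proportion,,,0.039,,,0.033,0.03
EMPA-KIDNEY,ethnicity_mixed,proportion,,,0.004,,,0.006,0.03
EMPA-KIDNEY,ethnicity_other,proportion,,,0.009,,,0.006,0.03
EMPA-KIDNEY,t2d,proportion,,,0.445,,,0.537,0.18
EMPA-KIDNEY,cvd,proportion,,,0.261,,,0.480,0.47
EMPA-KIDNEY,heart_failure,proportion,,,0.098,,,0.237,0.38
EMPA-KIDNEY,sbp,mean_sd,136.4,18.1,,135.6,17.9,,0.04
EMPA-KIDNEY,dbp,mean_sd,78.1,11.7,,73.6,11.2,,0.39
EMPA-KIDNEY,bmi,mean_sd,29.7,6.7,,29.4,6.2,,0.05
EMPA-KIDNEY,egfr,mean_sd,37.4,14.5,,44.1,14.4,,0.46
EMPA-KIDNEY,egfr_lt30,proportion,,,0.342,,,0.105,0.59
EMPA-KIDNEY,egfr_30_45,proportion,,,0.444,,,0.640,0.40
EMPA-KIDNEY,egfr_ge45,proportion,,,0.214,,,0.255,0.10
EMPA-KIDNEY,acr_lt3,proportion,,,0.201,,,0.365,0.37
EMPA-KIDNEY,acr_3_30,proportion,,,0.281,,,0.305,0.05
EMPA-KIDNEY,acr_gt30,proportion,,,0.518,,,0.258,0.55
EMPA-KIDNEY,ras_inhibitor,proportion,,,0.857,,,1.000,0.58
EMPA-KIDNEY,diuretic,proportion,,,0.412,,,0.433,0.04
EMPA-KIDNEY,statin,proportion,,,0.663,,,0.700,0.08
EMPA-KIDNEY,sglt2i,proportion,,,1.000,,,0.115,3.92
CREDENCE,age,mean_sd,62.9,9.2,,72.4,11.2,,0.93
CREDENCE,female,proportion,,,0.346,,,0.327,0.04
CREDENCE,ethnicity_white,proportion,,,0.675,,,0.739,0.14
CREDENCE,ethnicity_asian,proportion,,,0.193,,,0.148,0.12
CREDENCE,ethnicity_black,proportion,,,0.051,,,0.054,0.01
CREDENCE,ethnicity_other,proportion,,,0.081,,,0.010,0.35
CREDENCE,current_smoker,proportion,,,0.155,,,0.110,0.13
CREDENCE,cvd,proportion,,,0.505,,,0.378,0.26
CREDENCE,heart_failure,proportion,,,0.149,,,0.173,0.07
CREDENCE,hypertension,proportion,,,0.968,,,0.922,0.20
CREDENCE,sbp,mean_sd,139.8,15.6,,140.5,18.5,,0.04
CREDENCE,dbp,mean_sd,78.2,9.4,,75.6,11.5,,0.25
CREDENCE,bmi,mean_sd,31.4,6.2,,31.0,6.6,,0.06
CREDENCE,hba1c,mean_sd,67.2,14.2,,64.9,13.8,,0.16
CREDENCE,egfr,mean_sd,56.3,18.2,,58.7,16.7,,0.14
CREDENCE,egfr_15_30,proportion,,,0.038,,,0.000,0.28
CREDENCE,egfr_30_45,proportion,,,0.270,,,0.257,0.03
CREDENCE,egfr_45_60,proportion,,,0.286,,,0.286,0.00
CREDENCE,egfr_60_90,proportion,,,0.358,,,0.457,0.20
CREDENCE,egfr_ge90,proportion,,,0.048,,,0.000,0.32
CREDENCE,acr_lt3,proportion,,,0.007,,,0.000,0.12
CREDENCE,acr_3_30,proportion,,,0.114,,,0.000,0.51
CREDENCE,acr_30_300,proportion,,,0.773,,,0.951,0.53
CREDENCE,acr_gt300,proportion,,,0.106,,,0.049,0.21
CREDENCE,diuretic,proportion,,,0.466,,,0.372,0.19
CREDENCE,statin,proportion,,,0.698,,,0.853,0.38
CREDENCE,sglt2i,proportion,,,1.000,,,0.266,2.35
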