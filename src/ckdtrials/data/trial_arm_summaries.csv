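trial,variable,kind,n,mean,sd,proportion,median,q1,q3
CREDENCE,age,mean_sd,2202,62.9,9.2,,,,
CREDENCE,female,proportion,2202,,,0.346,,,
CREDENCE,ethnicity_white,proportion,2202,,,0.675,,,
CREDENCE,ethnicity_asian,proportion,2202,,,0.193,,,
CREDENCE,ethnicity_black,proportion,2202,,,0.051,,,
CREDENCE,ethnicity_other,proportion,2202,,,0.081,,,
CREDENCE,current_smoker,proportion,2202,,,0.155,,,
CREDENCE,cvd,proportion,2202,,,0.505,,,
CREDENCE,heart_failure,proportion,2202,,,0.149,,,
CREDENCE,hypertension,proportion,2202,,,0.968,,,
CREDENCE,sbp,mean_sd,2202,139.8,15.6,,,,
CREDENCE,dbp,mean_sd,2202,78.2,9.4,,,,
CREDENCE,bmi,mean_sd,2202,31.4,6.2,,,,
CREDENCE,hba1c,mean_sd,2202,67.2,14.2,,,,
CREDENCE,egfr,mean_sd,2202,56.3,18.2,,,,
CREDENCE,acr,median_iqr,2202,,,,104.3,51.9,202.7
CREDENCE,ras_inhibitor,proportion,2202,,,1.0,,,
CREDENCE,diuretic,proportion,2202,,,0.466,,,
CREDENCE,statin,proportion,2202,,,0.698,,,
CREDENCE,sglt2i,proportion,2202,,,1.0,,,
DAPA-CKD,age,mean_sd,2152,61.8,12.1,,,,
DAPA-CKD,female,proportion,2152,,,0.329,,,
DAPA-CKD,ethnicity_white,proportion,2152,,,0.522,,,
DAPA-CKD,ethnicity_asian,proportion,2152,,,0.348,,,
DAPA-CKD,ethnicity_black,proportion,2152,,,0.048,,,
DAPA-CKD,ethnicity_other,proportion,2152,,,0.081,,,
DAPA-CKD,current_smoker,proportion,2152,,,0.132,,,
DAPA-CKD,t2d,proportion,2152,,,0.676,,,
DAPA-CKD,cvd,proportion,2152,,,0.378,,,
DAPA-CKD,heart_failure,proportion,2152,,,0.109,,,
DAPA-CKD,sbp,mean_sd,2152,136.7,17.5,,,,
DAPA-CKD,dbp,mean_sd,2152,77.5,10.7,,,,
DAPA-CKD,bmi,mean_sd,2152,29.4,6.0,,,,
DAPA-CKD,weight,mean_sd,2152,81.5,20.1,,,,
DAPA-CKD,egfr,mean_sd,2152,43.2,12.3,,,,
DAPA-CKD,acr,median_iqr,2152,,,,109.1,53.3,215.0
DAPA-CKD,ras_inhibitor,proportion,2152,,,0.984,,,
DAPA-CKD,acei,proportion,2152,,,0.313,,,
DAPA-CKD,arb,proportion,2152,,,0.671,,,
DAPA-CKD,diuretic,proportion,2152,,,0.431,,,
DAPA-CKD,statin,proportion,2152,,,0.648,,,
DAPA-CKD,sglt2i,proportion,2152,,,1.0,,,
EMPA-KIDNEY,age,mean_sd,3304,63.9,13.9,,,,
EMPA-KIDNEY,female,proportion,3304,,,0.332,,,
EMPA-KIDNEY,ethnicity_white,proportion,3304,,,0.587,,,
EMPA-KIDNEY,ethnicity_asian,proportion,3304,,,0.361,,,
EMPA-KIDNEY,ethnicity_black,proportion,3304,,,0.039,,,
EMPA-KIDNEY,ethnicity_mixed,proportion,3304,,,0.004,,,
EMPA-KIDNEY,ethnicity_other,proportion,3304,,,0.009,,,
EMPA-KIDNEY,t1d,proportion,3304,,,0.010,,,
EMPA-KIDNEY,t2d,proportion,3304,,,0.445,,,
EMPA-KIDNEY,cvd,proportion,3304,,,0.261,,,
EMPA-KIDNEY,heart_failure,proportion,3304,,,0.098,,,
EMPA-KIDNEY,sbp,mean_sd,3304,136.4,18.1,,,,
EMPA-KIDNEY,dbp,mean_sd,3304,78.1,11.7,,,,
EMPA-KIDNEY,bmi,mean_sd,3304,29.7,6.7,,,,
EMPA-KIDNEY,egfr,mean_sd,3304,37.4,14.5,,,,
EMPA-KIDNEY,acr,median_iqr,3304,,,,37.4,5.2,119.9
EMPA-KIDNEY,ras_inhibitor,proportion,3304,,,0.857,,,
EMPA-KIDNEY,diuretic,proportion,3304,,,0.412,,,
EMPA-KIDNEY,statin,proportion,3304,,,0.663,,,
EMPA-KIDNEY,sglt2i,proportion,3304,,,1.0,,,
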