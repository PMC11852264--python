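label,trial,stratum,numerator,denominator,printed_percent
ckd_prevalence,,adults,516491,6670829,7.7
credence_all_ckd,CREDENCE,all_CKD,4740,516491,0.9
credence_ckd_t2d,CREDENCE,CKD_T2D,4740,169443,2.8
dapa_all_ckd,DAPA-CKD,all_CKD,11516,516491,2.2
dapa_ckd_t2d,DAPA-CKD,CKD_T2D,8036,169443,4.7
dapa_ckd_no_t2d,DAPA-CKD,CKD_no_T2D,3480,347048,1.0
empa_all_ckd,EMPA-KIDNEY,all_CKD,41209,516491,8.0
empa_ckd_t2d,EMPA-KIDNEY,CKD_T2D,22114,169443,13.1
empa_ckd_no_t2d,EMPA-KIDNEY,CKD_no_T2D,19095,347048,5.5
credence_complete_case,CREDENCE,all_CKD_complete_case,4740,367386,1.3
dapa_complete_case,DAPA-CKD,all_CKD_complete_case,11516,367386,3.1
empa_complete_case,EMPA-KIDNEY,all_CKD_complete_case,38214,367386,10.4
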