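patient_id,age,sex,diagnosis,fever,wbc,neutrophils_pct,eosinophils_pct,monocytes_pct,crp
P1,10,M,bronchiectasis,no,2.16,36.0,0.1,10.7,5.7
P2,13,M,bronchial asthma,no,5.45,47.0,4.4,6.0,12.0
P3,7,F,bronchial asthma,no,14.13,42.5,6.2,4.0,0.8
P4,6,M,bronchiectasis,no,4.96,50.9,1.2,5.8,6.5
P5,11,M,bronchitis,yes,5.99,50.3,4.6,9.0,44.7
P6,8,F,bronchiectasis,no,7.53,53.6,2.3,7.0,2.9
P7,16,F,bronchial asthma,no,4.33,58.4,2.0,4.7,0.8
P8,12,F,bronchiectasis,no,7.36,43.8,3.4,7.3,1.0
P9,14,M,bronchial asthma,no,4.34,46.2,0.7,7.0,4.2
P10,7,F,bronchial asthma,no,7.87,45.6,4.6,5.9,10.5
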