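patient_id,sex,gfr_ml_min,cycle,aa_gbq,weight_kg,tumour_ad_gy,kidney_ad_gy,tumour_teff_h,kidney_teff_h
P1,F,144,1,2.86,37.2,21.3,2.60,54.0,85.5
P1,F,144,2,3.67,42.8,11.4,3.18,39.0,71.3
P1,F,144,3,4.68,42.8,32.9,1.47,26.5,43.8
P1,F,144,4,4.25,44.0,6.6,4.02,31.2,47.0
P2,M,77,1,1.45,19.0,13.5,1.00,43.6,109.5
P2,M,77,2,2.16,22.6,11.4,1.03,37.8,102.0
P2,M,77,3,2.57,23.6,17.7,1.66,20.0,69.8
P2,M,77,4,2.86,25.4,0.72,1.81,29.8,73.4
P3,M,115,1,1.54,21.4,8.12,1.28,51.0,153.1
P3,M,115,2,2.00,24.2,9.67,1.19,37.7,93.4
P3,M,115,3,2.07,25.8,2.73,1.28,24.8,87.9
P3,M,115,4,2.15,27.1,10.4,1.98,25.9,118.4
P4,F,122,1,2.55,33.0,17.7,1.53,40.9,39.8
P4,F,122,2,3.61,35.7,24.9,1.59,40.3,82.4
P4,F,122,3,3.54,37.2,7.5,2.87,22.9,86.7
P4,F,122,4,3.60,38.2,20.1,2.82,35.5,57.8
P5,M,83,1,1.55,20.0,11.8,0.66,57.8,91.7
P5,M,83,2,2.08,19.6,11.3,0.66,47.6,132.9
P5,M,83,3,2.04,21.0,4.15,1.77,25.8,95.0
P5,M,83,4,2.39,21.8,1.92,1.79,35.1,26.9
P6,F,122,1,3.05,34.5,26.4,2.32,56.2,102.5
P6,F,122,2,4.11,39.5,28.8,3.20,43.8,146.1
P6,F,122,3,3.70,42.9,15.2,3.03,30.5,52.0
P6,F,122,4,4.71,46.1,1.00,3.03,32.5,100.6
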