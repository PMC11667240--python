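group,patient,age_y,sex,bmi_kg_m2,egfr_ml_min,lesion_numbers
tumor,1,30,F,24,84,1
tumor,2,67,M,26,72,2
tumor,3,59,M,26,66,3
tumor,4,64,M,22,32,4
tumor,5,68,M,25,90,5
tumor,6,35,F,34,120,6
pseudotumor,7,64,M,25,21,7
pseudotumor,8,68,M,27,63,8
pseudotumor,9,47,F,30,,9
pseudotumor,10,64,F,28,98,10
pseudotumor,11,63,M,29,97,11;12
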