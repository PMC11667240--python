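group,lesion,loop_duration_s,lesion_area_cm2,lesion_density_per_cm2,cortex_area_cm2,cortex_density_per_cm2
tumor,1,20,2.9,7,0.9,18
tumor,2,21,4.7,9,1.2,23
tumor,3,20,1.5,20,0.9,25
tumor,4,26,1.7,13,3.3,22
tumor,5,17,2.2,8,1.0,22
tumor,6,23,3.8,4,0.8,15
pseudotumor,7,20,1.1,29,0.8,35
pseudotumor,8,40,1.2,27,1.3,29
pseudotumor,9,10,1.7,22,0.9,26
pseudotumor,10,10,1.2,26,0.6,35
pseudotumor,11,17,1.3,19,0.7,28
pseudotumor,12,19,1.5,32,0.6,33
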