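group,lesion,frame_rate_hz,loop_duration_s,depth_mm,time_after_injection
tumor,1,43,20,18,02:40
tumor,2,32,21,26,05:23
tumor,3,43,20,27,04:02
tumor,4,39,26,15,03:05
tumor,5,43,17,13,03:36
tumor,6,32,23,39,02:42
pseudotumor,7,49,20,35,01:29
pseudotumor,8,32,40,32,03:33
pseudotumor,9,56,10,68,03:45
pseudotumor,10,39,10,36,01:15
pseudotumor,11,43,17,38,02:10
pseudotumor,12,43,19,40,02:05
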