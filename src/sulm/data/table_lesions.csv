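group,lesion,diagnosis,diagnostic_method,renal_side,renal_score,max_diameter_mm
tumor,1,Renal angiomyolipoma,CT/MRI,Right,10x,24
tumor,2,Papillary renal cell carcinoma,Partial nephrectomy,Right,8a,42
tumor,3,Clear cell renal cell carcinoma,Biopsy,Left,6p,21
tumor,4,Papillary renal neoplasm with reverse polarity,Biopsy,Renal graft,7x,17
tumor,5,Renal tubule mucinous spindle cell carcinoma,Biopsy,Right,5x,27
tumor,6,Renal angiomyolipoma,CT/MRI,Left,8x,51
pseudotumor,7,Hypertrophy of the column of Bertin,MRI,Renal graft,10x,35
pseudotumor,8,Hypertrophy of the column of Bertin,CT/MRI,Renal graft,9x,19
pseudotumor,9,Focal compensatory hypertrophy,Biopsy,Right,5p,41
pseudotumor,10,Hypertrophy of the column of Bertin,CT/MRI,Right,9a,19
pseudotumor,11,Hypertrophy of the column of Bertin,CT,Right,7p,25
pseudotumor,12,Hypertrophy of the column of Bertin,CT,Left,6a,16
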