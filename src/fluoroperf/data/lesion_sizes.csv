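polyp_id,pathology,mean_estimate_mm,actual_mm,fully_visible
S1,benign,60,120,False
S2,cancer,20,29,True
S3,benign,44,46,True
S4,benign,37,30,True
S5,benign,20,18,True
S6,cancer,26,24,True
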