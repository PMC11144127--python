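polyp_id,pathology,majority_answer,majority_pct,mean_likert,n_1,n_2,n_3,n_4,n_5
P01,benign,benign,53,3.28,0,4,16,11,1
P02,cancer,cancer,69,3.38,0,2,17,12,1
P03,cancer,benign,72,3.06,1,5,17,9,0
P04,benign,cancer,75,3.59,0,1,14,14,3
P05,benign,benign,78,3.16,1,5,16,8,2
P06,cancer,benign,63,3.22,0,6,15,9,2
P07,benign,cancer,91,3.53,0,4,12,11,5
P08,cancer,cancer,91,3.84,0,1,9,16,6
P09,benign,benign,75,3.13,1,8,10,12,1
P10,cancer,benign,63,3.31,1,4,14,10,3
P11,benign,benign,73,2.94,0,12,12,6,2
P12,benign,cancer,97,3.53,0,3,13,12,4
P13,cancer,benign,78,2.91,1,9,15,6,1
P14,cancer,even,50,3.16,0,7,16,6,3
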