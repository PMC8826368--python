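subject_id,age,gender,head_cm,cap_cm,AQ,AQ_S,AQ_C,AQ_A,AQ_D,AQ_I
B1,5,M,51.5,52,21,1,4,7,5,4
B2,5,M,51,52,32,6,7,3,10,6
B3,13,M,57,56,26,6,3,4,7,6
B4,12,M,56,56,44,8,8,11,13,4
B5,12,M,56,56,25,1,4,10,0,10
B6,6,F,53,52,17,1,1,4,8,3
B7,7,M,53,52,24,2,4,11,2,5
B8,4,F,50.5,52,38,6,11,7,11,3
B9,4,M,52,52,42,11,11,11,3,6
B10,4,M,51,52,,,,,,
B11,9,F,54,56,28,2,6,3,13,4
B12,8,M,54.5,56,26,4,5,5,4,8
B13,4,M,53,56,44,11,9,8,9,7
B14,6,M,53,52,36,5,2,3,19,7
B15,7,M,51.5,52,49,12,8,10,9,10
B16,10,F,55,56,48,9,9,10,10,10
B17,10,M,54,56,40,9,5,7,13,6
B18,4,F,49.5,52,19,2,3,5,6,3
B19,7,M,54,56,19,2,3,5,6,3
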