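subject_id,age,gender,head_cm,cap_cm,AQ,AQ_S,AQ_C,AQ_A,AQ_D,AQ_I
A1,29,F,57,56,11,0,1,7,1,2
A2,36,F,56,56,17,0,0,6,9,2
A3,35,M,57,56,17,3,3,5,0,6
A4,28,F,57,56,3,0,0,1,1,1
A5,25,F,57,56,19,4,1,7,6,1
A6,35,F,57,56,15,4,2,4,5,0
A7,29,F,57,56,11,0,2,5,3,1
A8,30,F,56,56,13,0,2,4,5,2
A9,29,F,59,56,7,1,1,3,2,0
A10,29,M,58,56,12,1,1,5,4,1
A11,27,M,56.5,56,17,2,3,5,4,3
A12,30,F,56,56,9,1,2,2,3,1
A13,29,M,57,56,14,1,3,6,2,2
A14,36,M,58.5,56,19,2,2,5,7,3
A15,36,M,57,56,16,4,1,4,5,2
A16,29,F,54,56,22,1,3,9,7,2
A17,28,F,58.5,56,7,1,0,2,1,3
A18,29,F,55,56,12,0,1,5,5,1
A19,34,M,60,56,19,6,2,5,5,1
A20,26,M,58,56,10,3,0,5,2,0
A21,36,F,56,56,15,1,2,2,7,3
A22,30,M,60.5,56,19,1,2,6,4,6
A23,26,F,56,56,12,0,1,5,6,0
A24,32,M,60.5,56,7,0,1,5,0,1
A25,34,F,56,56,10,1,1,4,2,2
A26,29,F,57,56,32,6,5,8,9,4
A27,31,M,59,56,32,10,6,6,2,8
A28,39,F,57,56,21,2,4,4,8,3
A29,29,M,57,56,6,0,0,2,2,2
A30,29,M,57,56,17,3,2,5,6,1
A31,36,M,59.5,56,12,0,0,6,4,2
A32,27,M,59,56,12,1,2,5,2,2
A33,40,M,57,56,13,2,3,1,6,1
A34,31,F,55,56,15,1,1,4,4,5
A35,27,M,56.5,56,19,6,2,4,7,0
A36,30,M,58,56,14,5,1,3,4,1
A37,25,M,58,56,29,6,8,6,7,2
A38,31,M,57.5,56,10,0,1,5,3,1
A39,38,M,57.5,56,25,2,4,6,8,5
A40,33,F,57.5,56,13,0,0,3,10,0
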