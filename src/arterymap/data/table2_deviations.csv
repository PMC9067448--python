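patient,left_Fa,left_IL,left_SL,left_Ang,left_LN,left_DN,left_STr,left_SO,left_ST,right_Fa,right_IL,right_SL,right_Ang,right_LN,right_DN,right_STr,right_SO,right_ST
1,0,0,0,0,0,—,0,—,5,0,—,—,0,0,0,0,—,3
2,2,—,—,—,0,—,0,—,0,—,—,—,0,0,—,—,—,0
3,0,0,—,0,—,—,0,—,0,0,0,0,0,0,—,—,—,0
4,3,—,—,—,—,—,2,2,0,3,—,—,—,—,—,0,0,0
5,0,—,—,0,0,—,0,—,0,0,—,—,0,0,—,0,—,0
6,3,—,0,3,0,—,0,0,0,2,—,—,0,—,—,0,—,0
7,3,—,0,2,0,—,0,0,0,2,—,3,2,0,—,0,0,0
8,0,0,0,1,0,—,2,0,0,0,—,—,0,1,—,2,0,0
9,0,—,0,0,0,—,0,—,4,0,—,0,0,0,—,0,—,0
10,0,—,0,0,0,—,0,0,0,0,—,0,0,0,—,0,0,0
11,—,—,—,—,0,—,0,—,0,0,—,—,0,0,—,0,—,0
12,0,—,0,2,2,0,0,0,0,0,0,0,2,—,0,0,—,0
13,—,—,0,0,2,—,0,0,0,—,—,—,,—,—,0,—,0
14,—,—,—,—,—,2,0,0,2,0,—,0,0,—,—,0,0,2
15,—,0,0,—,—,0,0,0,4,—,—,0,2,—,0,0,—,2
16,0,—,—,0,—,0,2,2,0,0,—,—,0,—,—,0,0,0
17,0,—,—,0,0,—,0,—,0,0,—,—,0,0,—,0,—,0
18,0,0,0,0,0,—,0,—,3,0,—,2,0,0,—,0,—,0
19,0,—,—,0,0,—,0,0,0,—,—,—,0,—,0,0,—,0
20,—,—,—,0,—,—,—,—,0,—,—,—,0,—,0,0,—,0
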