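position,base,frac_to_A,frac_to_C,frac_to_G,frac_to_T
5,A,0.0,0.003,0.003,0.003
6,C,0.005,0.0,0.005,0.005
7,C,0.007,0.0,0.007,0.007
8,A,0.0,0.0015,0.0015,0.0015
9,A,0.0,0.003,0.0035,0.0035
10,T,0.005,0.0055,0.0055,0.0
11,C,0.007,0.0,0.0075,0.0075
12,C,0.0015,0.0,0.0015,0.002
13,A,0.0,0.0035,0.0035,0.004
14,A,0.0,0.0055,0.0055,0.006
15,C,0.0075,0.0,0.0075,0.0075
16,A,0.0,0.002,0.002,0.002
17,T,0.004,0.004,0.004,0.0
18,C,0.006,0.0,0.006,0.006
19,C,0.0075,0.0,0.008,0.008
20,A,0.0,0.002,0.0025,0.0025
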