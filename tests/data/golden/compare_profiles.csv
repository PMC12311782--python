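position,base,x,y
5,A,0.0135,0.01
6,C,0.02,0.0165
7,C,0.0265,0.023
8,A,0.008,0.0045
9,A,0.0145,0.011
11,C,0.0025,0.024
12,C,0.009,0.0055
13,A,0.0155,0.012
14,A,0.022,0.0185
15,C,0.0035,0.025
16,A,0.01,0.0065
18,C,0.023,0.0195
19,C,0.0045,0.026
20,A,0.011,0.0075
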