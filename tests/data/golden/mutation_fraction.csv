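position,base,fraction
5,A,0.01
6,C,0.0165
7,C,0.023
8,A,0.0045
9,A,0.011
10,T,0.0175
11,C,0.024
12,C,0.0055
13,A,0.012
14,A,0.0185
15,C,0.025
16,A,0.0065
17,T,0.013
18,C,0.0195
19,C,0.026
20,A,0.0075
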