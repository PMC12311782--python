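position,base,delta
5,A,0.0034999999999999996
6,C,0.0034999999999999996
7,C,0.0034999999999999996
8,A,0.0035000000000000005
9,A,0.0035000000000000014
11,C,-0.021500000000000002
12,C,0.0034999999999999996
13,A,0.0034999999999999996
14,A,0.0034999999999999996
15,C,-0.021500000000000002
16,A,0.0035000000000000005
18,C,0.0034999999999999996
19,C,-0.0215
20,A,0.0034999999999999996
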