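position,base,coverage
3,A,2000
4,C,2000
5,A,2000
6,C,2000
7,C,2000
8,A,2000
9,A,2000
11,C,2000
12,C,2000
13,A,2000
14,A,2000
15,C,2000
16,A,2000
18,C,2000
19,C,2000
20,A,2000
24,A,2000
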