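bin_left,bin_right,count
0,1,18
1,2,17
2,3,17
3,4,17
4,5,17
5,6,17
6,7,17
7,8,0
8,9,0
9,10,0
10,11,0
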