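rank,reference,r_squared,n,responder
1.0,ref1,0.0012555693504210242,14,True
2.0,ref2,0.13028435787299827,13,True
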