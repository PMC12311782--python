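sample,value,unit,fraction
s0,0.0,mM,0.023
s10,10.0,mM,0.0265
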