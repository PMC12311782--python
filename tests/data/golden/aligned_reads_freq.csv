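bin_left,bin_right,count
2000.0,2010.0,1
2010.0,2020.0,0
2020.0,2030.0,0
2030.0,2040.0,0
2040.0,2050.0,1
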