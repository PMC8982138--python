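sample_id,taxA,taxB,taxC
s1,5,10,15
s2,4,1,0
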