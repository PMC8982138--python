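sample_id,taxA,taxB
s1,1,2
s2,3,0
s3,0,0
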