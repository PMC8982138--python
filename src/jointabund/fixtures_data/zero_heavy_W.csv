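sample_id,taxA,taxB,taxC,taxD
s1,0,3,0,0
s2,2,0,0,1
s3,0,0,0,5
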