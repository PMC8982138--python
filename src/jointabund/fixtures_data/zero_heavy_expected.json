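{
  "undefined_scaling_sample": {
    "value": "s3",
    "provenance": "trivial: zero observed reads in s3"
  },
  "zero_fraction": {
    "value": 0.6666666666666666,
    "provenance": "derived: 8 zeros of 12 cells"
  }
}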