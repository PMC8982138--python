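{
  "M": {"value": [7], "provenance": "trivial: single-taxon closure M = W"}
}
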