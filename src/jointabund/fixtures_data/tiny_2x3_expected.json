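{
  "scaling_factor": {"value": [2.0, 2.0], "provenance": "derived: direct arithmetic (30/15, 10/5)"},
  "mu_hat": {"value": [[10.0, 20.0, 30.0], [8.0, 2.0, 0.0]], "provenance": "derived: s_i * W_ij"},
  "M": {"value": [30, 5], "provenance": "trivial: row sums"}
}
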