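{
 "description": "SYNTHETIC demonstration covariance for the uncertainty-propagation procedure. No estimation covariance is published with the model parameters; this diagonal matrix assigns log-scale coefficients of variation of 10-30% to selected rates and exists only to exercise the sampling/band/coverage pipeline.",
 "scale_map": {
  "k_int": "log",
  "kon3": "log",
  "koff3": "log",
  "k_out": "log",
  "kon_A": "log"
 }
}
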