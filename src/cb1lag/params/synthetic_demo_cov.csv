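label,k_int,kon3,koff3,k_out,kon_A
k_int,0.01,0.0,0.0,0.0,0.0
kon3,0.0,0.04,0.0,0.0,0.0
koff3,0.0,0.0,0.09,0.0,0.0
k_out,0.0,0.0,0.0,0.0225,0.0
kon_A,0.0,0.0,0.0,0.0,0.04
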