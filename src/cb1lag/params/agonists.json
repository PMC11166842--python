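{
 "CP": {
  "pKd": 8.6,
  "k_int": 0.15,
  "log10_eps": 1.66,
  "citation": {
   "pKd": "estimated (unified CB1/ORG model, Yang et al. 2022)",
   "k_int": "estimated (unified CB1/ORG model, Yang et al. 2022)",
   "log10_eps": "Zhu et al.",
   "kon3": "reference value; inherited from the CP55940/ORG estimate"
  }
 },
 "WIN": {
  "pKd": 7.7,
  "k_int": 0.28,
  "log10_eps": 2.63,
  "citation": {
   "pKd": "Brizzi et al.",
   "k_int": "Zhu et al.",
   "log10_eps": "Zhu et al.",
   "kon3": "fixed to the CP55940/ORG value"
  }
 },
 "THC": {
  "pKd": 8.0,
  "k_int": 0.029,
  "log10_eps": 0.85,
  "citation": {
   "pKd": "Cheng et al.",
   "k_int": "Zhu et al.",
   "log10_eps": "Zhu et al.",
   "kon3": "fixed to the CP55940/ORG value"
  }
 },
 "THC_calibrated": {
  "pKd": 8.0,
  "k_int": 0.029,
  "log10_eps": 0.85,
  "kon3": 0.05,
  "citation": {
   "pKd": "Cheng et al.",
   "k_int": "Zhu et al.",
   "log10_eps": "Zhu et al.",
   "kon3": "calibrated by aligning kinetic cAMP data (ten-fold below the CP55940 value)"
  }
 }
}
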