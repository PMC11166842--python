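{
 "agonist": {
  "pKd": {
   "value": 8.6,
   "unit": "-log10(M)",
   "provenance": "printed"
  },
  "k_int": {
   "value": 0.15,
   "unit": "1/min",
   "provenance": "printed"
  },
  "log10_eps": {
   "value": 1.66,
   "unit": "log10(dimensionless)",
   "provenance": "printed"
  },
  "kon_A": {
   "value": 10.0,
   "unit": "1/(uM*min)",
   "provenance": "calibrated"
  }
 },
 "allosteric": {
  "kon3": {
   "value": 0.528,
   "unit": "1/(uM*min)",
   "provenance": "printed"
  },
  "koff3": {
   "value": 0.01,
   "unit": "1/min",
   "provenance": "calibrated"
  },
  "kon2": {
   "value": 1.0,
   "unit": "1/(uM*min)",
   "provenance": "calibrated"
  },
  "Kd_B": {
   "value": 1.0,
   "unit": "uM",
   "provenance": "calibrated"
  },
  "k_TI": {
   "value": 1.0,
   "unit": "1/min",
   "provenance": "calibrated"
  },
  "K_TI_eq": {
   "value": 1.0,
   "unit": "dimensionless",
   "provenance": "calibrated"
  },
  "k_int_T": {
   "value": null,
   "unit": "1/min",
   "provenance": "calibrated"
  }
 },
 "system": {
  "R0": {
   "value": 1.0,
   "unit": "fraction of R0",
   "provenance": "derived"
  },
  "k_syn_R": {
   "value": 0.0,
   "unit": "R0/min",
   "provenance": "calibrated"
  },
  "eps_R": {
   "value": 1.0,
   "unit": "dimensionless",
   "provenance": "printed"
  },
  "I50": {
   "value": 1.0031707317073173,
   "unit": "R0-equivalents",
   "provenance": "derived"
  },
  "Imax": {
   "value": 1.0,
   "unit": "dimensionless",
   "provenance": "derived"
  },
  "k_in": {
   "value": 0.023,
   "unit": "response/min",
   "provenance": "calibrated"
  },
  "k_out": {
   "value": 0.023,
   "unit": "1/min",
   "provenance": "calibrated"
  }
 }
}
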