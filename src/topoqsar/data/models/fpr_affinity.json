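{
  "name": "fpr_affinity",
  "intercept": 76.50,
  "terms": {
    "ww": 0.000033,
    "MAXDN": -9.50,
    "BELm5": -15.68,
    "GGI10": -3.18,
    "VEA1": -5.12
  },
  "response": "logki"
}
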