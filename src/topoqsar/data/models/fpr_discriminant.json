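{
  "name": "fpr_discriminant",
  "intercept": 245.5,
  "terms": {
    "Cchi1p": -296.2,
    "Dchi4pc": 50.2,
    "W": -0.0034,
    "V4": 4.4
  },
  "response": "DF",
  "domain_window": [-8.0, 8.0]
}
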