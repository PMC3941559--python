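{
  "outcome": "FVC",
  "intercept": -8.572,
  "coef": {
    "height_m": 5.108,
    "thorax_cm": 0.138,
    "mobility_l": 0.120
  },
  "R": 0.931,
  "R2": 0.866,
  "SEE_l": 0.353,
  "n": 40
}
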