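{
  "outcome": "DI",
  "intercept": -6.373,
  "coef": {
    "height_m": 3.751,
    "thorax_cm": 0.122,
    "mobility_l": 0.163
  },
  "R": 0.881,
  "R2": 0.815,
  "SEE_l": 0.451,
  "n": 40
}
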