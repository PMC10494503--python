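{
  "name": "eq2",
  "description": "Free 25(OH)D estimating equation 2: equation 1 variables plus additive VDBP (Gc) diplotype offsets against reference Gc1f/Gc1f",
  "intercept": 12.779,
  "terms": [
    ["albumin", "identity", 0.348],
    ["d25_3", "log", 0.748],
    ["vdbp", "log", -1.566],
    ["d25_2", "log", 0.149],
    ["d1_25_3", "log", -0.833],
    ["d24_25_3", "log", -1.826]
  ],
  "interactions": [
    ["d25_3", "d24_25_3", 0.935]
  ],
  "phenotype_offsets": {
    "Gc1f/Gc1f": 0.0,
    "Gc1f/Gc1s": 0.019716,
    "Gc1s/Gc1s": 0.002741,
    "Gc2/Gc1f": -0.394562,
    "Gc2/Gc1s": -0.1283514,
    "Gc2/Gc2": -0.1381116
  },
  "metadata": {
    "adj_r2": 0.583,
    "rmse_development": 1.164,
    "rmse_validation": 1.165
  }
}
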