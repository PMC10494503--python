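{
  "name": "eq3",
  "description": "Free 25(OH)D estimating equation 3 (clinical-laboratory variables only): albumin, 25(OH)D3, iPTH, 1,25(OH)2D3",
  "intercept": 3.098,
  "terms": [
    ["albumin", "identity", 0.275],
    ["d25_3", "log", 2.370],
    ["ipth", "log", -0.467],
    ["d1_25_3", "log", -1.194]
  ],
  "interactions": [],
  "phenotype_offsets": {},
  "metadata": {
    "adj_r2": 0.514,
    "rmse_development": 1.257,
    "rmse_validation": 1.353
  }
}
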