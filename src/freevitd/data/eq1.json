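{
  "name": "eq1",
  "description": "Free 25(OH)D estimating equation 1: albumin, 25(OH)D3, 25(OH)D2, VDBP, 1,25(OH)2D3, 24,25(OH)2D3, with a log[25(OH)D3] x log[24,25(OH)2D3] interaction",
  "intercept": 12.202,
  "terms": [
    ["albumin", "identity", 0.359],
    ["d25_3", "log", 0.844],
    ["d25_2", "log", 0.145],
    ["vdbp", "log", -1.522],
    ["d1_25_3", "log", -0.851],
    ["d24_25_3", "log", -1.906]
  ],
  "interactions": [
    ["d25_3", "d24_25_3", 0.943]
  ],
  "phenotype_offsets": {},
  "metadata": {
    "adj_r2": 0.586,
    "rmse_development": 1.159,
    "rmse_validation": 1.161
  }
}
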