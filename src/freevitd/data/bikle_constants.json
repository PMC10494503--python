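{
  "name": "bikle_constants",
  "description": "Single-site equilibrium constants for the Bikle free 25(OH)D calculation: affinities of VDBP and albumin for 25(OH)D and the molecular weights used to convert clinical mass units to molar",
  "ka_dbp": 8.00e8,
  "ka_alb": 6.00e5,
  "mw_25ohd": 400.64,
  "mw_vdbp": 58000.0,
  "mw_albumin": 66430.0
}
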