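{
  "name": "secretion_tgf",
  "interpolation": "monotone-piecewise",
  "conc_units": "pg/uL",
  "resp_units": "dimensionless",
  "clamp_below": true,
  "clamp_above": true
}
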