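{
  "d_Mphi": 0.6,
  "rho_Mphi": 2500.0,
  "rho_F": 1250.0,
  "rho_C": 3300.0,
  "k_F": 0.924,
  "d_F": 0.12,
  "k_MphiT": 0.07,
  "k_FT": 0.004,
  "d_Tbeta": 15.0,
  "k_MphiM9": 3.0,
  "d_M9": 0.875,
  "k_on": 0.0003,
  "k_off": 0.0004,
  "k_onc": 0.004,
  "k_FC": 20.0,
  "T_betaN": 6.0,
  "d_mc": 0.05,
  "frac_endo_smc": 0.17,
  "frac_myocyte": 0.56,
  "kinetic_time_unit": "per-day-as-printed",
  "u_T0": 0.0,
  "d_CID": 0.0
}
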