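{
  "schema_version": 1,
  "model": "modified",
  "params": {
    "alpha_O": 0.18,
    "beta_O": 0.02,
    "g_O": 0.088,
    "alpha_P": 0.04,
    "beta_P": 0.04,
    "g_P": 0.13,
    "l1": 0.13,
    "l2": 0.009,
    "m1": 0.09,
    "m2": 0.07,
    "contact_scaling": "frequency"
  },
  "initial": {"S": 628, "O": 626, "P": 626},
  "N": 1880,
  "t_end": 2000.0,
  "n_points": 400
}
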