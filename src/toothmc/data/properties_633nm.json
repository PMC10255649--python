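{
  "wavelength_nm": 633,
  "ambient_n": 1.0,
  "media": {
    "bounding": {"mu_a": 10.0, "mu_s": 10.0, "g": 0.9, "n": 1.0},
    "enamel":   {"mu_a": 0.04, "mu_s": 1.5,  "g": 0.7,  "n": 1.63},
    "dentin":   {"mu_a": 0.30, "mu_s": 26.0, "g": 0.93, "n": 1.54},
    "pulp":     {"mu_a": 0.035, "mu_s": 10.0, "g": 0.97, "n": 1.39}
  }
}
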