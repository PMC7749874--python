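{
  "air": {"density_g_cm3": 0.0012047, "z_over_a": 0.49919},
  "water": {"density_g_cm3": 1.0, "z_over_a": 0.55509},
  "soft_tissue": {"density_g_cm3": 1.06, "z_over_a": 0.54996},
  "pmma": {"density_g_cm3": 1.19, "z_over_a": 0.53937},
  "bone": {"density_g_cm3": 1.92, "z_over_a": 0.51478},
  "aluminum": {"density_g_cm3": 2.699, "z_over_a": 0.48181}
}
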