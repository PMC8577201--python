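# Soil N depth profile at 63 DAP (4 layers x {NH4, NO3} x 2 N treatments).
# Encoded effects: ammonium is 11 % of total available N in the top 15 cm of
# the high-N soil and 21 % in the low-N soil; concentrations decay
# geometrically with depth.  Absolute concentrations (mg N per kg soil) are
# invented at magnitudes typical of fertilised silt loams.
name: soil
kind: soil
soil:
  layers: ["0-15", "15-30", "30-45", "45-60"]
  treatments:
    HN:
      topsoil_total_n: 60.0   # mg N / kg soil, total NH4+NO3 in 0-15 cm
      nh4_fraction_top: 0.11
    LN:
      topsoil_total_n: 15.0
      nh4_fraction_top: 0.21
  depth_decay: 0.55           # layer-to-layer multiplier
  noise_cv: 0.0
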