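# Greenhouse trial, ammonium as the sole N source (RCBD, 6 RILs x 4 blocks).
# Encoded effects: no RHL plasticity under low ammonium; low N lowers shoot
# biomass by 23 % and raises root:shoot by ~13 %; under low N the trait-vs-RHL
# line climbs 44 % (biomass) and 71 % (plant N) across the RHL range.
# Absolute trait scales and noise levels are invented (flagged), the ratios
# and multipliers are the encoded effects.
name: ghI
kind: greenhouse
n_form: ammonium
n_rils: 6
n_blocks: 4
baseline_rhl_mm: [0.2, 1.0]
treatments: [HN, LN]
rhl_treatment_multiplier:
  HN: 1.0
  LN: 1.0          # ammonium stress leaves RHL unchanged
trait_means_hn:    # invented scales (per plant, 35 DAP)
  shoot_g: 14.0
  root_g: 4.5
  root_length_cm: 6000.0
  n_content_mg: 350.0
trait_treatment_multiplier:
  LN:
    shoot_g: 0.77        # -23 %
    root_g: 0.87         # with shoot -23 % => root:shoot +13 %
    root_length_cm: 1.0  # unaffected
    n_content_mg: 0.60   # invented
endpoint_ratio:
  HN: {}
  LN:
    shoot_g: 1.44        # +44 % across the RHL range
    n_content_mg: 1.71   # +71 %
noise:
  trait_cv: 0.10
  rhl_cv: 0.08
  block_sd_frac: 0.03
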