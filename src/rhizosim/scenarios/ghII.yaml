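# Greenhouse trial, nitrate as the sole N source (RCBD, 6 RILs x 4 blocks).
# Encoded effects: low nitrate raises RHL by 21 % and lowers shoot biomass by
# 55 %; under low N the trait-vs-RHL line climbs 216 % (biomass) and 237 %
# (plant N) across the RHL range.  Absolute scales and noise are invented.
name: ghII
kind: greenhouse
n_form: nitrate
n_rils: 6
n_blocks: 4
baseline_rhl_mm: [0.2, 1.0]
treatments: [HN, LN]
rhl_treatment_multiplier:
  HN: 1.0
  LN: 1.21         # +21 % RHL under low nitrate
trait_means_hn:    # invented scales (per plant, 35 DAP)
  shoot_g: 14.0
  root_g: 4.5
  root_length_cm: 6000.0
  n_content_mg: 350.0
trait_treatment_multiplier:
  LN:
    shoot_g: 0.45        # -55 %
    root_g: 0.55         # invented
    root_length_cm: 0.80 # invented
    n_content_mg: 0.35   # invented
endpoint_ratio:
  HN: {}
  LN:
    shoot_g: 3.16        # +216 % across the RHL range
    n_content_mg: 3.37   # +237 %
noise:
  trait_cv: 0.10
  rhl_cv: 0.08
  block_sd_frac: 0.03
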