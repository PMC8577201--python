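# Field trial (split-plot: N level on whole plots, 9 RILs on subplots,
# 3 replicates).  Encoded effects: low N lowers RHL by 30 %, shoot biomass at
# flowering by 45 % and yield by 12 %; under low N the trait-vs-RHL line
# climbs 250 % (shoot), 200 % (plant N) and 267 % (yield) across the RHL
# range.  The shoot-biomass noise CV is calibrated so the emergent low-N
# regression R^2 sits in the 0.2-0.35 band typical of such field data; other
# CVs are set to agronomically typical values.  Absolute scales invented.
name: field
kind: field
n_form: urea
n_rils: 9
n_blocks: 3        # replicates (whole blocks)
baseline_rhl_mm: [0.2, 1.0]
treatments: [HN, LN]
rhl_treatment_multiplier:
  HN: 1.0
  LN: 0.70         # -30 % RHL under low N in the field
trait_means_hn:    # invented scales (per plant, 63 DAP; yield at maturity)
  leaf_area_cm2: 4500.0
  shoot_g: 120.0
  yield_g: 150.0
  n_content_mg: 1800.0
trait_treatment_multiplier:
  LN:
    shoot_g: 0.55        # -45 %
    yield_g: 0.88        # -12 %
    leaf_area_cm2: 0.70  # invented
    n_content_mg: 0.55   # invented
endpoint_ratio:
  HN: {}
  LN:
    shoot_g: 3.50        # +250 % across the RHL range
    n_content_mg: 3.00   # +200 %
    yield_g: 3.67        # +267 %
    leaf_area_cm2: 2.50  # invented (association reported, size not printed)
noise:
  trait_cv:
    shoot_g: 0.55        # calibrated: low-N shoot R^2 in 0.2-0.35
    leaf_area_cm2: 0.50
    yield_g: 0.10
    n_content_mg: 0.30
  rhl_cv: 0.08
  block_sd_frac: 0.03
  whole_plot_sd_frac: 0.03
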