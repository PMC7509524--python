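# Packaged desk-scale run: 5000 individuals x 500 SNPs, sub-additive
# diabetes x PRS interaction, every pipeline stage exercised.
output_dir: out/small
simulation:
  n_individuals: 5000
  n_variants: 500
  n_causal: 20
  seed: 2025
  interaction_specs: [[diabetes, -0.4]]
split:
  train_fraction: 0.3
  seed: 11
prs:
  reference_panel_size: 503
selection:
  n_bootstrap: 100
  seed: 5
interaction:
  n_bootstrap: 200
  seed: 7
  exposures: [smoking_ever, low_alcohol, depression, daytime_sleepiness, diabetes]
evaluation:
  n_bootstrap: 100
  seed: 9
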