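# Hexane-like synthetic umbrella-sampling study.
# Presets supply the 11-window ladder (4-14 A, k = 2 kcal/mol/A^2), the
# nine temperatures, five ionic strengths and the ground-truth potential;
# anything listed here overrides the preset.
preset: hexane

conditions:
  ionic_strengths: [0.0, 1.0, 2.0]
  # temperatures: [273, 285, 298, 310, 323, 335, 348, 360, 373]
  # n_samples: 50000

wham:
  bin_width: 0.1
  tol: 1.0e-7
  n_boot: 20
  block_len: 200

features:
  smooth_window: 3
  min_prominence: 0.05

thermo:
  eval_T: 298.0
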