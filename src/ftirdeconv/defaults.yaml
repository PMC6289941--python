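# Default configuration for `ftirdeconv run`.
# Any key may be overridden by the user config; dictionaries merge shallowly.

mode: full
output_dir: ftirdeconv_out
seed: 0
grid_step: 1.0

baseline:
  amide_anchors: [1590.0, 1710.0]
  fingerprint_anchors: [900.0, 1200.0]

derivative:
  window_points: 13
  polyorder: 3

subtraction:
  reference_region: [1000.0, 1150.0]

fit:
  region: [1600.0, 1700.0]
  center_slack: 5.0
  fwhm_min: 8.0
  fwhm_max: 40.0
  fwhm_init: 16.0
  eta_mode: fixed
  eta_fixed: 0.5
  max_bands: 8
  r2_accept: 0.9999
  min_ss_improvement: 0.2
  prominence_frac: 0.05

stats:
  alpha: 0.05
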