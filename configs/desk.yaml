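# Desk-scale profile: 64x64 phantoms, small network, CPU-friendly.
seed: 0
out_dir: runs/desk

forge:
  n: 200
  height: 64
  width: 64
  liver_axes: [22.0, 16.0]
  n_tumors: [0, 3]
  tumor_radius_range: [3.0, 7.0]
  tumor_contrast: 0.25
  noise_sd: 0.04

prep:
  split: [0.7, 0.2, 0.1]
  sigma_s: 1.5
  sigma_r: 0.1
  blur_sigma: 0.5
  denoise: true
  augment: false
  rotations: [80, 90, 180, 270]

model:
  input_size: 64
  levels: 2
  base_filters: 8
  inception_kernels: [1, 3, 5]
  inception_modules: 1
  bottleneck_ratio: 0.5
  # desk-width branches carry 2-4 channels; the full-scale 0.3 rate is far
  # too destructive there, so the desk profile regularizes lightly
  dropout: 0.1
  use_residual: true
  use_historic_stamp: true
  use_pyramid_pool: false
  out_channels: 1

train:
  learning_rate: 0.001
  batch_size: 8
  epochs: 12
  early_stop_patience: 6

loss:
  w_focal: 0.27
  w_dice: 0.69
  w_hausdorff: 0.04
  focal_alpha: 0.25
  focal_gamma: 2.0

go:
  population: 12
  iterations: 15
  sparsity: 0.05

classifier:
  learning_rate: 0.05
  max_depth: 6
  num_leaves: 40
  feature_fraction: 0.9
  bagging_fraction: 0.8
  n_rounds: 100
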