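# Full-scale profile mirroring the published settings (512x512 input,
# 4 encoder levels, batch 32, 100 epochs, GO population 25 x 100 generations).
# This profile assumes external data volumes and long training; it is not
# exercised by the test suite.
seed: 0
out_dir: runs/paper

forge:
  n: 2000
  height: 512
  width: 512
  liver_axes: [180.0, 130.0]
  n_tumors: [0, 3]
  tumor_radius_range: [12.0, 50.0]
  tumor_contrast: 0.25
  noise_sd: 0.04

prep:
  split: [0.7, 0.2, 0.1]
  sigma_s: 1.5
  sigma_r: 0.1
  blur_sigma: 0.5
  denoise: true
  augment: true
  rotations: [80, 90, 180, 270]

model:
  input_size: 512
  levels: 4
  base_filters: 64
  inception_kernels: [1, 3, 5]
  inception_modules: 3
  bottleneck_ratio: 0.5
  dropout: 0.3
  use_residual: true
  use_historic_stamp: true
  use_pyramid_pool: true
  out_channels: 1

train:
  learning_rate: 0.001
  batch_size: 32
  epochs: 100
  early_stop_patience: 15

loss:
  w_focal: 0.27
  w_dice: 0.69
  w_hausdorff: 0.04
  focal_alpha: 0.25
  focal_gamma: 2.0

go:
  population: 25
  iterations: 100
  sparsity: 0.05

classifier:
  learning_rate: 0.05
  max_depth: 6
  num_leaves: 40
  feature_fraction: 0.9
  bagging_fraction: 0.8
  n_rounds: 100
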