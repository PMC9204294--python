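# Shipped defaults: preprocessing, phantom simulation, model, and training
# protocol. Any subset may be overridden by a user config file.
preprocessing:
  clip: [-1.0, 2.5]
  # Crop corner (0-based voxels) placing the 80x100x80 patch over both
  # hippocampi on the MNI152 181x217x181 1mm grid; override per study.
  crop_corner: [50, 52, 16]
  crop_size: [80, 100, 80]

simulate:
  shape: [80, 100, 80]
  n_per_class: 100
  signal_radius_nc: 8.0
  atrophy_fraction: 0.3
  noise_sd: 0.5
  n_redundant_blobs: 6
  morph_dim: 3
  morph_effect: [-1.5, -0.8, 1.2]
  seed: 0

model:
  channels: [8, 16, 32, 64, 128]
  latent_dim: 100
  hidden_sizes: [64, 32]
  sample_inference: false

train:
  lr_base: 0.0005
  batch_size: 32
  epochs: 120
  warmup_epochs: 2
  decay_every: 40
  decay_factor: 5.0
  train_fraction: 0.8
  alpha: 10.0
  weight_decay: 0.05
  seeds: [0, 1, 2, 3, 4]

grid:
  alphas: [0.1, 0.5, 1, 5, 10, 20]
  latent_dims: [0, 1, 30, 50, 100]
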