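# Tiny configuration for smoke tests and CLI examples (completes in seconds).
seed: 0
task:
  kind: latency_images
  n_classes: 3
  n_channels: 36
  samples_per_class: 12
network:
  n_hidden: 16
training:
  n_epochs: 2
  batch_size: 12
experiment:
  seeds: [1]
  sigma_grid: [0.0, 0.3]
  rho_b_grid: [0.0, 0.01]
  dropout_rates: [0.0, 0.4]
  ablation_fractions: [0.0, 0.3]
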