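# Sparsity sweep: accuracy vs. hidden spike count across rho_b.
seed: 0
task:
  kind: latency_images
  n_classes: 10
  n_channels: 70
  samples_per_class: 100
network:
  n_hidden: 64
training:
  n_epochs: 20
  batch_size: 32
  lr: 0.003
experiment:
  seeds: [1, 2, 3]
  rho_b_grid: [0.0, 0.001, 0.01, 0.1]
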