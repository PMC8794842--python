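# Self-calibration experiment: ITL training vs. software weight transfer
# across decalibration levels sigma_d on the synthetic latency task.
seed: 0
task:
  kind: latency_images
  n_classes: 10
  n_channels: 70
  samples_per_class: 100
network:
  n_hidden: 64
training:
  n_epochs: 30
  batch_size: 16
  lr: 0.003
experiment:
  seeds: [1, 2, 3]
  sigma_grid: [0.0, 0.3, 0.5]
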