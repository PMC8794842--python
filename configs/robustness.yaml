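# Dropout-vs-ablation robustness experiment (software backend: per-batch
# mask dropout needs long training runs).
seed: 0
substrate:
  enabled: false
task:
  kind: latency_images
  n_classes: 10
  n_channels: 70
  samples_per_class: 100
network:
  n_hidden: 64
training:
  n_epochs: 80
  batch_size: 50
  lr: 0.002
experiment:
  seeds: [1, 2, 3]
  dropout_rates: [0.0, 0.4]
  ablation_fractions: [0.0, 0.05, 0.15, 0.3]
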