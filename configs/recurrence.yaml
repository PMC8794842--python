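# Recurrent-vs-frozen-recurrent control on the order-sensitive temporal
# task. Short time constants force working memory into the recurrent
# connectivity (with tau_m = 20 dt the feed-forward PSPs alone span the
# whole pattern). Software backend: the contrast is a property of the
# trained connectivity, and the long runs it needs fit the budget there.
seed: 0
substrate:
  enabled: false
  tau_mem: 6.0
  tau_syn: 3.0
task:
  kind: temporal_patterns
  n_classes: 6
  n_channels: 70
  samples_per_class: 60
network:
  n_hidden: 64
  recurrent: true
loss:
  mode: sum_over_time
training:
  n_epochs: 80
  batch_size: 50
  lr: 0.002
experiment:
  seeds: [1, 2, 3]
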