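# Canonical design constants of the estimate-adjustment task.
#
# Layout offsets are each peer's distance from the first estimate as a
# multiple of the mean peer offset M; every triple averages to 1 so the
# mean peer offset is identical across conditions.
slider: [1, 200]
mean_offset_fraction: 0.4
layout_offsets:
  LN: [0.8, 1.0, 1.2]
  HN: [0.3, 1.0, 1.7]
  HF: [0.30, 1.35, 1.35]
  HC: [0.50, 0.50, 2.00]
session:
  n_condition_rounds: 5
  n_filler: 10
  n_control: 5
  pool_size: 100
scenarios:
  low_value: 50
  high_value: 150
  split_agent_E1: 75
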