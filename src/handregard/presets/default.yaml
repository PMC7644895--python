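# Training condition: one "other" with visual value 0.2 roaming the whole
# workspace; hands visible at 0.5; corollary discharge on.
stimulus:
  hand_visual: 0.5
  other_visual: 0.2
  n_others: 1
  hand_visual_on: true
  corollary_on: true
  confine_others: false
learning:
  eta: 0.1
  alpha: 0.1
  update_interval: 10
  move_threshold: 0.5
  init_bound: 0.1
checkpoint_interval: 1000000
eval_steps: 10000
assembly_threshold: 0.9
seeds: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
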