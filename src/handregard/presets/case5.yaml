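# Test case 5: others confined to the field of view.
stimulus:
  hand_visual: 0.5
  other_visual: 0.5
  n_others: 5
  hand_visual_on: true
  corollary_on: true
  confine_others: true
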