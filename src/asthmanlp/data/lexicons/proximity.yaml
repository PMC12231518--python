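chest_tightness:
  anchors_a: [tight, tightness, tighter]
  anchors_b: [chest]
  max_gap: 3
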