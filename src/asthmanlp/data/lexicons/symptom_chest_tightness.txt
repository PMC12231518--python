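# Chest tightness direct phrases; the proximity rule in proximity.yaml
# additionally matches tight/tightness ... chest within 3 words, either order.
chest tightness
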