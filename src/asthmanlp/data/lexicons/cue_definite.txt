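# Definite affirmation cues.
positive for
pos for
confirmed
endorses
endorsed
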