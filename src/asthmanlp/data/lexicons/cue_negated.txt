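# Negation cues (pre-position).
no
not
denies
denied
deny
denying
without
negative for
neg for
no evidence of
absence of
never
free of
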