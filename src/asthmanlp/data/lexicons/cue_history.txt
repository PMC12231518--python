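# Historical / remote-timeframe cues.
history of
a couple of months before
months ago
weeks ago
years ago
last year
last month
previously
in the past
as a child
childhood
since childhood
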