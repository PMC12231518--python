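# Cough terms (one phrase per line, pre-normalized lowercase).
cough
coughing
coughs
coughed
coughing fits
productive cough
dry cough
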