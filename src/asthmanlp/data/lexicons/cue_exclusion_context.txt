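# Context-exclusion terms: symptoms co-documented with these are not
# attributed to asthma (default scope: anywhere in the note).
anxiety
anxious
panic attack
panic attacks
panic disorder
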