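# Uncertain / probable cues.
likely
possible
possibly
probable
probably
suspect
suspected
questionable
concern for
may have
might have
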