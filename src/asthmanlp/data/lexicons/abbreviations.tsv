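sob	shortness of breath
doe	dyspnea on exertion
pt	patient
hx	history
c o	complains of
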