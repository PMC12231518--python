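# Dyspnea terms.
dyspnea
dyspneic
shortness of breath
short of breath
sob
breathlessness
difficulty breathing
trouble breathing
labored breathing
dyspnea on exertion
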