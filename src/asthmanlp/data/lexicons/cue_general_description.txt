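# Templated warning / education language; symptoms under these cues are
# generic descriptions, not patient findings.
please return if
return if
if you experience
if you develop
if you notice
call if
call us if
seek medical attention if
go to the emergency department if
warning signs
symptoms may include
watch for
education provided regarding
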