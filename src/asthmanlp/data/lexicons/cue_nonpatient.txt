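# Non-patient person cues (family members, other persons).
daughter
son
mother
father
brother
sister
wife
husband
grandmother
grandfather
roommate
friend
family member
coworker
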