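# class <TAB> template. {symptom} is replaced by a surface phrase drawn from
# the shipped lexicons; {other}/{other2} by non-symptom distractors.
affirmed	patient reports {symptom} today .
affirmed	presents with {symptom} .
affirmed	{symptom} noted on exam .
affirmed	reports {symptom} since yesterday .
affirmed	patient states the {symptom} is worse at night .
negated	no {symptom} .
negated	denies {symptom} .
negated	negative for {symptom} .
negated	patient denies {symptom} at this time .
negated	no evidence of {symptom} on exam .
list_negated	denies {other} , {other2} , or {symptom} .
list_negated	no {symptom} , {other} , or {other2} .
list_negated	negative for {other} , {symptom} , and {other2} .
uncertain	likely {symptom} .
uncertain	possible {symptom} noted .
uncertain	patient may have {symptom} .
history	history of {symptom} .
history	had {symptom} years ago .
history	{symptom} started a couple of months before .
nonpatient	his daughter has {symptom} .
nonpatient	mother reports {symptom} at home .
nonpatient	her son was seen for {symptom} .
general_description	please return if you experience {symptom} .
general_description	call if {symptom} worsens .
general_description	watch for {symptom} or {other} .
anxiety_context	patient reports {symptom} today .
anxiety_context	presents with {symptom} .
adversarial_long_list	denied {other} , {other2} , {symptom} , {other3} , or any new medication .
adversarial_post_negation	{symptom} is denied .
adversarial_post_negation	patient states {symptom} has not been present .
filler	vital signs stable .
filler	lungs clear to auscultation .
filler	afebrile today .
filler	follow up in two weeks .
filler	medication refill provided .
filler	tolerating diet well .
filler	sleeping well at night .
filler	no acute distress .
instruction_filler	take medications as prescribed .
instruction_filler	please call the office with any questions .
instruction_filler	return if symptoms worsen .
anxiety_marker	patient reports anxiety .
anxiety_marker	ongoing anxiety discussed .
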