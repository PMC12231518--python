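"""Run the rule engine on tricky sentences and inspect its reasoning.

Each (sentence, symptom) pair gets exactly one reason code; a symptom is
'Yes' only when a mention is affirmed (or uncertain, which counts as
present by default).
"""

from asthmanlp import (
    ClinicalNote,
    SYMPTOMS,
    classify_note,
    default_config,
    load_lexicons,
    preprocess_note,
)

prep = default_config()
lex = load_lexicons()

EXAMPLES = [
    "No wheezing, mild SOB.",                      # negation stops at "mild"
    "Denied fever, chills, wheezes, GERD, or any new medication.",
    "No wheezing or dyspnea but chest feels tight.",
    "His daughter has a chronic cough.",           # not the patient
    "Cough started a couple of months before.",    # history, not current
    "Please return if you experience cough or wheezing.",  # warning template
]

for text in EXAMPLES:
    note = ClinicalNote(note_id="demo", patient_id="p", text=text)
    sentences = preprocess_note(note, prep)
    labels, _ = classify_note(sentences, lex)
    print(text)
    for sl in labels:
        for sym in SYMPTOMS:
            if sl.reasons[sym] != "NO_MENTION":
                print(f"   {sym:16s} {sl.labels[sym]:3s}  ({sl.reasons[sym]})")
    print()
print("Reason codes explain every No: negated, history, non-patient,")
print("general warning text, excluded section, or anxiety context.")
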