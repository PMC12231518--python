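"""Generate a small synthetic note corpus with gold labels and look inside.

The generator emulates how asthma symptoms are actually documented in
clinical notes — affirmed, negated (singly or over denial lists),
uncertain, historical, family-member, templated-warning and
anxiety-context mentions — and emits the labels an annotator would assign
under the same reading rules.
"""

from asthmanlp import SYMPTOMS, SynthConfig, generate_corpus

corpus = generate_corpus(SynthConfig(n_notes=5, seed=42))

for sn in corpus[:2]:
    print(f"--- {sn.note.note_id} ({sn.note.note_type}, {sn.note.department})")
    print(sn.note.text)
    print("note-level gold:", {s: sn.note_gold.labels[s] for s in SYMPTOMS})
    print()

n_pos = sum(
    any(v == "Yes" for v in sn.note_gold.labels.values()) for sn in corpus
)
print(f"{n_pos}/{len(corpus)} notes carry at least one true symptom.")
print("A 'Yes' here means the patient currently has that symptom according")
print("to the generating template, not merely that the word appears.")
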