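"""Surface misspellings/synonyms of a symptom term with word embeddings.

Lexicon curation is human work; this is the lookup that feeds it.  We train
a small skip-gram model on a synthetic corpus in which "weezing" appears in
the same contexts as "wheezing", then ask for the nearest neighbors — the
misspelling should surface near the top of the ranked list.
"""

import numpy as np

from asthmanlp import nearest_terms, train_embedding

rng = np.random.default_rng(0)
contexts = [
    ["patient", "reports", "{}", "today"],
    ["mild", "{}", "noted", "on", "exam"],
    ["worsening", "{}", "at", "night"],
    ["no", "{}", "on", "auscultation"],
]
corpus = []
for _ in range(150):
    template = contexts[int(rng.integers(len(contexts)))]
    word = "wheezing" if rng.random() < 0.5 else "weezing"
    corpus.append([t.format(word) if t == "{}" else t for t in template])

model = train_embedding(corpus, dimension=24, window=3, epochs=40, seed=2)
neighbors = nearest_terms(model, "wheezing", 5)
print("top-5 neighbors of 'wheezing':", neighbors)
print("'weezing' ranking near the top is the signal a curator would use to")
print("add it to the misspelling table.")
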