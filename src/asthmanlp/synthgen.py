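"""Seeded generator of synthetic clinical notes with known gold labels.

Real clinical corpora of this kind are proprietary, so the generator
emulates the documentation patterns such notes exhibit — affirmed, negated,
list-negated, uncertain, historical, non-patient, templated-warning and
anxiety-context symptom mentions, spread over sectioned multi-sentence notes
with configurable abbreviation and misspelling rates — and emits the
adjudicated labels a human annotator would assign under the same reading
rules.  It exists for testing, for training the desk-scale classifier, and
for benchmarking; it makes no claim of clinical realism beyond this pattern
taxonomy, and identifiers are opaque synthetic strings.

Sentence counts per note follow a negative binomial with mean ~11 (the
scale of deployment-time notes, which are much shorter than enriched
annotated ones); every note draws each symptom independently with its
configured mention probability.  Deliberate misspellings and abbreviations
come from curated tables whose members the preprocessing standardizer
provably repairs, so they perturb the surface text without perturbing gold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import NO, SYMPTOMS, YES, ClinicalNote, GoldRecord
from .lexicon import LexiconSet, load_lexicons
from .rule_engine import NoteLabelSet

#: Context classes whose mention is a true patient finding (gold Yes,
#: absent anxiety suppression elsewhere in the note).
POSITIVE_CLASSES = frozenset({"affirmed", "uncertain", "anxiety_context"})
#: Classes the shipped rule patterns fully cover (the 100%-recovery set).
COVERED_CLASSES = frozenset(
    {
        "affirmed",
        "negated",
        "list_negated",
        "uncertain",
        "history",
        "nonpatient",
        "general_description",
        "anxiety_context",
    }
)
ADVERSARIAL_CLASSES = frozenset({"adversarial_long_list", "adversarial_post_negation"})

_DISTRACTORS = ("fever", "chills", "nausea", "headache", "dizziness", "sore throat", "gerd")

#: Deliberate misspellings the distance-1 corrector uniquely repairs.
_MISSPELLINGS = {
    "wheezing": "weezing",
    "cough": "coug",
    "dyspnea": "dyspnia",
    "tightness": "tightnes",
    "breath": "breth",
}
#: Abbreviated surface forms (standardization expands them back).
_ABBREVIATIONS = {
    "shortness of breath": "sob",
    "dyspnea on exertion": "doe",
}
#: Extra chest-tightness realizations exercising the proximity rule.
_TIGHTNESS_SURFACES = ("tightness in the chest", "chest feels tight", "tight chest")


@dataclass(frozen=True)
class SynthConfig:
    n_notes: int = 100
    sentences_per_note_mean: float = 11.2
    sentences_per_note_dispersion: float = 0.4
    mention_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "cough": 0.30,
            "dyspnea": 0.25,
            "wheezing": 0.20,
            "chest_tightness": 0.15,
        }
    )
    class_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "affirmed": 0.45,
            "negated": 0.20,
            "list_negated": 0.10,
            "uncertain": 0.05,
            "history": 0.07,
            "nonpatient": 0.05,
            "general_description": 0.05,
            "anxiety_context": 0.03,
            "adversarial_long_list": 0.0,
            "adversarial_post_negation": 0.0,
        }
    )
    abbreviation_prob: float = 0.15
    misspelling_prob: float = 0.10
    instructions_prob: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for p in list(self.mention_prob.values()) + [
            self.abbreviation_prob,
            self.misspelling_prob,
            self.instructions_prob,
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"context-class probabilities must sum to 1, got {total}")
        if any(p < 0 for p in self.class_probs.values()):
            raise ValueError("context-class probabilities must be nonnegative")
        if set(self.mention_prob) != set(SYMPTOMS):
            raise ValueError("mention_prob must cover exactly the four symptoms")
        unknown = set(self.class_probs) - COVERED_CLASSES - ADVERSARIAL_CLASSES
        if unknown:
            raise ValueError(f"unknown context classes: {unknown}")


def covered_only(config: SynthConfig) -> SynthConfig:
    """A copy of ``config`` with adversarial class probabilities zeroed."""
    probs = {c: p for c, p in config.class_probs.items() if c in COVERED_CLASSES}
    total = sum(probs.values())
    probs = {c: p / total for c, p in probs.items()}
    return SynthConfig(
        **{
            **{f: getattr(config, f) for f in config.__dataclass_fields__},
            "class_probs": probs,
        }
    )


@dataclass(frozen=True)
class SynthNote:
    note: ClinicalNote
    gold: tuple[GoldRecord, ...]
    note_gold: NoteLabelSet
    #: per-sentence tag: a context class, "filler", "instruction_filler",
    #: "anxiety_marker", or "header".
    classes: tuple[str, ...]
    #: per-sentence symptom realized by that sentence ("" for none).
    symptoms: tuple[str, ...]


def _load_templates() -> dict[str, list[str]]:
    source = resources.files("asthmanlp").joinpath("data", "templates", "templates.tsv")
    out: dict[str, list[str]] = {}
    for line in source.read_text(encoding="utf-8").splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cls, _, template = line.partition("\t")
        out.setdefault(cls, []).append(template)
    return out


def _surface(sym: str, lex: LexiconSet, rng: np.random.Generator, cfg: SynthConfig) -> str:
    """Pick a surface phrase for a symptom, possibly abbreviated/misspelled."""
    choices = list(lex.symptom_terms[sym])
    if sym == "chest_tightness":
        choices += list(_TIGHTNESS_SURFACES)
    phrase = choices[int(rng.integers(len(choices)))]
    if phrase in _ABBREVIATIONS and rng.random() < cfg.abbreviation_prob:
        return _ABBREVIATIONS[phrase]
    if rng.random() < cfg.misspelling_prob:
        tokens = phrase.split()
        hits = [i for i, t in enumerate(tokens) if t in _MISSPELLINGS]
        if hits:
            i = hits[int(rng.integers(len(hits)))]
            tokens[i] = _MISSPELLINGS[tokens[i]]
            return " ".join(tokens)
    return phrase


def _realize(template: str, sym: str, lex, rng, cfg) -> str:
    text = template.replace("{symptom}", _surface(sym, lex, rng, cfg))
    others = rng.choice(len(_DISTRACTORS), size=3, replace=False)
    for slot, idx in zip(("{other}", "{other2}", "{other3}"), others):
        text = text.replace(slot, _DISTRACTORS[int(idx)])
    return text


def generate_corpus(config: SynthConfig, lex: LexiconSet | None = None) -> list[SynthNote]:
    """Generate a corpus of synthetic notes with sentence/note gold labels.

    Deterministic for a fixed config (the seed is part of the config).  A
    sentence's gold label for its symptom is Yes iff its context class is in
    ``POSITIVE_CLASSES`` and no anxiety-context mention occurs anywhere in
    the note; the note-level gold is the OR of sentence golds.
    """
    lex = lex or load_lexicons()
    templates = _load_templates()
    rng = np.random.default_rng(config.seed)
    class_names = sorted(config.class_probs)
    class_p = np.array([config.class_probs[c] for c in class_names])

    m = config.sentences_per_note_mean
    r = config.sentences_per_note_dispersion
    nb_p = r / (r + m)

    notes: list[SynthNote] = []
    for i in range(config.n_notes):
        note_id = f"note{i:06d}"
        patient_id = f"pat{int(rng.integers(10_000)):05d}"

        # (class, symptom, text) triples; one mention sentence per symptom.
        drawn: list[tuple[str, str, str]] = []
        for sym in SYMPTOMS:
            if rng.random() < config.mention_prob[sym]:
                cls = class_names[int(rng.choice(len(class_names), p=class_p))]
                template = templates[cls][int(rng.integers(len(templates[cls])))]
                drawn.append((cls, sym, _realize(template, sym, lex, rng, config)))

        anxiety = any(cls == "anxiety_context" for cls, _, _ in drawn)
        n_target = max(int(rng.negative_binomial(r, nb_p)), len(drawn) + 1)
        n_filler = max(n_target - len(drawn) - (1 if anxiety else 0), 1)
        body = list(drawn)
        for _ in range(n_filler):
            t = templates["filler"][int(rng.integers(len(templates["filler"])))]
            body.append(("filler", "", t))
        if anxiety:
            t = templates["anxiety_marker"][
                int(rng.integers(len(templates["anxiety_marker"])))
            ]
            body.append(("anxiety_marker", "", t))
        body = [body[int(j)] for j in rng.permutation(len(body))]

        tagged = [("header", "", "history of present illness .")] + body
        if rng.random() < config.instructions_prob:
            tagged.append(("header", "", "instructions ."))
            for _ in range(1 + int(rng.integers(2))):
                t = templates["instruction_filler"][
                    int(rng.integers(len(templates["instruction_filler"])))
                ]
                tagged.append(("instruction_filler", "", t))

        raw = " ".join(
            (t[0].upper() + t[1:]) if rng.random() < 0.3 else t
            for _, _, t in tagged
        )

        gold_records = []
        for idx, (cls, sym, _) in enumerate(tagged):
            labels = {s: NO for s in SYMPTOMS}
            if sym and cls in POSITIVE_CLASSES and not anxiety:
                labels[sym] = YES
            gold_records.append(
                GoldRecord(note_id=note_id, sentence_index=idx, labels=labels)
            )
        note_labels = {
            s: YES if any(g.labels[s] == YES for g in gold_records) else NO
            for s in SYMPTOMS
        }

        notes.append(
            SynthNote(
                note=ClinicalNote(
                    note_id=note_id,
                    patient_id=patient_id,
                    text=raw,
                    encounter_type="office visit",
                    note_type="progress note",
                    department=("allergy", "internal medicine", "pulmonology")[i % 3],
                ),
                gold=tuple(gold_records),
                note_gold=NoteLabelSet(note_id=note_id, labels=note_labels),
                classes=tuple(cls for cls, _, _ in tagged),
                symptoms=tuple(sym for _, sym, _ in tagged),
            )
        )
    return notes


def difficulty_split(
    corpus: Sequence[SynthNote],
) -> tuple[list[SynthNote], list[SynthNote]]:
    """Partition a corpus into (covered, adversarial) subsets.

    A note is adversarial iff any of its sentences carries an adversarial
    context-class tag (long denial lists, post-position negation); the split
    is disjoint and exhaustive.
    """
    covered = [n for n in corpus if not any(c in ADVERSARIAL_CLASSES for c in n.classes)]
    adversarial = [n for n in corpus if any(c in ADVERSARIAL_CLASSES for c in n.classes)]
    return covered, adversarial
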