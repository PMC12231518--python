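"""Rule-based symptom classifier: mention finding, cue scoping, exclusions.

For each sentence the engine finds symptom mentions (phrase matches plus
proximity-rule matches), finds context cues, works out which cues govern
which mentions, and emits one Yes/No label with a single reason code per
(sentence, symptom).  Note-level labels are the OR of sentence labels.

Scoping model
-------------
Cues fall into two families with different scope behavior:

* Polarity cues (``negated``, ``definite``, ``uncertain``) scope forward
  from the cue, distributing across comma/"or"/"and"-separated list items.
  Scope ends at a semicolon, at a contrast word ("but", "however"), at a
  later polarity cue of a different category, or at a list item that opens
  with an affirming qualifier ("no wheezing, mild sob": the negation stops
  before "mild sob").
* Attribution cues (``history``, ``nonpatient``, ``general_description``,
  ``exclusion_context``) scope over their whole semicolon-delimited clause
  in both directions — a temporal modifier like "a couple of months before"
  marks the clause's symptom regardless of word order.

When several cues govern one mention the category priority is
nonpatient > general_description > history > polarity; within the polarity
family the cue nearest the mention wins, which is how a definite cue
("positive for") overrides an earlier negation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .corpus_io import NO, SYMPTOMS, YES, NotePrediction, SentencePrediction
from .lexicon import CUE_CATEGORIES, LexiconSet
from .preprocess import Sentence

_PUNCT = {",", ";", ".", "?"}
_POLARITY = ("negated", "definite", "uncertain")
_ATTRIBUTION = ("history", "nonpatient", "general_description", "exclusion_context")

# Reason codes: exactly one per (sentence, symptom); Yes iff AFFIRMED or
# UNCERTAIN_AFFIRMED.  UNCERTAIN_EXCLUDED only appears under the non-default
# configuration that counts uncertain mentions as absent.
REASONS = (
    "AFFIRMED",
    "UNCERTAIN_AFFIRMED",
    "NO_MENTION",
    "NEGATED",
    "HISTORY",
    "NONPATIENT",
    "GENERAL_DESCRIPTION",
    "SECTION_EXCLUDED",
    "CONTEXT_EXCLUDED",
    "UNCERTAIN_EXCLUDED",
)
_YES_REASONS = {"AFFIRMED", "UNCERTAIN_AFFIRMED"}


@dataclass(frozen=True)
class SymptomMention:
    symptom: str
    start: int
    end: int  # exclusive
    evidence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid mention span")


@dataclass(frozen=True)
class CueMatch:
    category: str
    start: int
    end: int
    phrase: str


@dataclass(frozen=True)
class SentenceLabelSet:
    note_id: str
    sentence_index: int
    labels: Mapping[str, str]
    reasons: Mapping[str, str]
    evidence: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym in SYMPTOMS:
            label, reason = self.labels[sym], self.reasons[sym]
            if (label == YES) != (reason in _YES_REASONS):
                raise ValueError(f"label/reason mismatch for {sym}: {label}/{reason}")


@dataclass(frozen=True)
class NoteLabelSet:
    note_id: str
    labels: Mapping[str, str]


@dataclass(frozen=True)
class RuleConfig:
    """Tunable behavior of the rule engine.

    ``excluded_sections`` lists section labels whose sentences never yield a
    positive symptom (templated instruction text, questionnaires, stale
    problem lists).  ``context_scope`` controls the exclusion-context
    (anxiety) rule: ``"note"`` suppresses symptoms anywhere in a note that
    mentions anxiety, ``"sentence"`` only in the co-mentioning sentence.
    """

    excluded_sections: frozenset[str] = frozenset(
        {"instructions", "questionnaire", "problem_list"}
    )
    uncertain_is_present: bool = True
    context_scope: str = "note"  # "note" | "sentence"
    affirming_qualifiers: frozenset[str] = frozenset(
        {
            "mild",
            "moderate",
            "severe",
            "intermittent",
            "occasional",
            "persistent",
            "worsening",
            "chronic",
            "frequent",
            "slight",
        }
    )
    contrast_words: frozenset[str] = frozenset({"but", "however"})
    post_position_negation: bool = False


def _phrase_matches(tokens: Sequence[str], phrase: str) -> list[tuple[int, int]]:
    target = tuple(phrase.split())
    k = len(target)
    return [
        (i, i + k) for i in range(len(tokens) - k + 1) if tuple(tokens[i : i + k]) == target
    ]


def _collapse_longest(matches: list) -> list:
    """Drop matches overlapped by a longer (or earlier, equal-length) match."""
    kept: list = []
    for m in sorted(matches, key=lambda m: (-(m.end - m.start), m.start)):
        if all(m.end <= k.start or m.start >= k.end for k in kept):
            kept.append(m)
    return sorted(kept, key=lambda m: m.start)


def find_mentions(sentence: Sentence, lex: LexiconSet) -> list[SymptomMention]:
    """All maximal symptom phrase matches plus proximity-rule matches."""
    tokens = sentence.tokens
    out: list[SymptomMention] = []
    for sym in SYMPTOMS:
        matches = [
            SymptomMention(sym, s, e, phrase)
            for phrase in lex.symptom_terms[sym]
            for s, e in _phrase_matches(tokens, phrase)
        ]
        rule = lex.proximity_rules.get(sym)
        if rule is not None:
            pos_a = [i for i, t in enumerate(tokens) if t in rule.anchors_a]
            pos_b = [i for i, t in enumerate(tokens) if t in rule.anchors_b]
            for ia in pos_a:
                for ib in pos_b:
                    lo, hi = min(ia, ib), max(ia, ib)
                    gap = sum(1 for t in tokens[lo + 1 : hi] if t not in _PUNCT)
                    if gap <= rule.max_gap:
                        out_phrase = f"{tokens[lo]}...{tokens[hi]}" if hi > lo + 1 else (
                            f"{tokens[lo]} {tokens[hi]}"
                        )
                        matches.append(SymptomMention(sym, lo, hi + 1, out_phrase))
        out.extend(_collapse_longest(matches))
    return sorted(out, key=lambda m: (m.start, m.symptom))


def find_cues(sentence: Sentence, lex: LexiconSet) -> list[CueMatch]:
    """All whole-token cue phrase matches, longest match per category."""
    out: list[CueMatch] = []
    for cat in CUE_CATEGORIES:
        matches = [
            CueMatch(cat, s, e, phrase)
            for phrase in lex.cue_terms[cat]
            for s, e in _phrase_matches(sentence.tokens, phrase)
        ]
        out.extend(_collapse_longest(matches))
    return sorted(out, key=lambda c: (c.start, c.category))


def _segment_of(tokens: Sequence[str], index: int) -> tuple[int, int]:
    """Semicolon-delimited clause segment [lo, hi) containing ``index``."""
    lo = 0
    for i in range(index - 1, -1, -1):
        if tokens[i] == ";":
            lo = i + 1
            break
    hi = len(tokens)
    for i in range(index, len(tokens)):
        if tokens[i] == ";":
            hi = i
            break
    return lo, hi


def _forward_scope_end(
    cue: CueMatch,
    sentence: Sentence,
    cues: Sequence[CueMatch],
    config: RuleConfig,
) -> int:
    """First token index no longer governed by a forward-scoping cue."""
    tokens = sentence.tokens
    conflicting = {
        c.start
        for c in cues
        if c.category in _POLARITY and c.category != cue.category and c.start >= cue.end
    }
    i = cue.end
    while i < len(tokens):
        tok = tokens[i]
        if tok == ";" or tok in config.contrast_words or i in conflicting:
            return i
        if tok == ",":
            # peek at the next list item: an affirming qualifier opening it
            # breaks the distribution ("no wheezing, mild sob").
            j = i + 1
            while j < len(tokens) and tokens[j] in _PUNCT:
                j += 1
            if j < len(tokens) and tokens[j] in config.affirming_qualifiers:
                return i
        i += 1
    return len(tokens)


def scope_cue(
    cue: CueMatch,
    mentions: Sequence[SymptomMention],
    sentence: Sentence,
    config: RuleConfig | None = None,
    cues: Sequence[CueMatch] = (),
) -> list[SymptomMention]:
    """The mentions governed by ``cue`` in this sentence."""
    config = config or RuleConfig()
    if cue.category in _ATTRIBUTION:
        lo, hi = _segment_of(sentence.tokens, cue.start)
        return [m for m in mentions if lo <= m.start and m.end <= hi]
    end = _forward_scope_end(cue, sentence, cues, config)
    governed = [m for m in mentions if cue.end <= m.start < end]
    if config.post_position_negation and cue.category == "negated":
        lo, _ = _segment_of(sentence.tokens, cue.start)
        governed += [m for m in mentions if lo <= m.start and m.end <= cue.start]
    return governed


def _polarity_reason(
    mention: SymptomMention, governing: Sequence[CueMatch]
) -> str:
    polar = [c for c in governing if c.category in _POLARITY]
    if not polar:
        return "AFFIRMED"
    nearest = max(polar, key=lambda c: c.end)  # closest preceding cue wins
    if nearest.category == "definite":
        return "AFFIRMED"
    if any(c.category == "negated" for c in polar):
        return "NEGATED"
    return "UNCERTAIN_AFFIRMED"


def _mention_reason(
    mention: SymptomMention,
    cues: Sequence[CueMatch],
    sentence: Sentence,
    config: RuleConfig,
) -> str:
    governing = [
        c for c in cues if mention in scope_cue(c, [mention], sentence, config, cues)
    ]
    cats = {c.category for c in governing}
    if "nonpatient" in cats:
        return "NONPATIENT"
    if "general_description" in cats:
        return "GENERAL_DESCRIPTION"
    if "history" in cats:
        return "HISTORY"
    if config.context_scope == "sentence" and "exclusion_context" in cats:
        return "CONTEXT_EXCLUDED"
    return _polarity_reason(mention, governing)


def classify_sentence(
    sentence: Sentence,
    lex: LexiconSet,
    config: RuleConfig | None = None,
    note_context_excluded: bool = False,
) -> SentenceLabelSet:
    """Label one preprocessed sentence for all four symptoms.

    ``note_context_excluded`` is set by :func:`classify_note` when the
    note-scoped exclusion-context rule (anxiety anywhere in the note) is in
    force.
    """
    config = config or RuleConfig()
    mentions = find_mentions(sentence, lex)
    cues = find_cues(sentence, lex)
    sentence_context = config.context_scope == "sentence" and any(
        c.category == "exclusion_context" for c in cues
    )

    labels: dict[str, str] = {}
    reasons: dict[str, str] = {}
    evidence: dict[str, str] = {}
    for sym in SYMPTOMS:
        sym_mentions = [m for m in mentions if m.symptom == sym]
        if not sym_mentions:
            labels[sym], reasons[sym] = NO, "NO_MENTION"
            evidence[sym] = ""
            continue
        evidence[sym] = sym_mentions[0].evidence
        if sentence.section in config.excluded_sections:
            labels[sym], reasons[sym] = NO, "SECTION_EXCLUDED"
            continue
        if note_context_excluded and config.context_scope == "note":
            labels[sym], reasons[sym] = NO, "CONTEXT_EXCLUDED"
            continue
        per_mention = [
            (m, _mention_reason(m, cues, sentence, config)) for m in sym_mentions
        ]
        affirmed = [mr for mr in per_mention if mr[1] in _YES_REASONS]
        if affirmed:
            mention, reason = min(
                affirmed, key=lambda mr: (mr[1] != "AFFIRMED", mr[0].start)
            )
            if reason == "UNCERTAIN_AFFIRMED" and not config.uncertain_is_present:
                labels[sym], reasons[sym] = NO, "UNCERTAIN_EXCLUDED"
            else:
                labels[sym], reasons[sym] = YES, reason
            evidence[sym] = mention.evidence
        else:
            labels[sym], reasons[sym] = NO, per_mention[0][1]
            evidence[sym] = per_mention[0][0].evidence
    return SentenceLabelSet(
        note_id=sentence.note_id,
        sentence_index=sentence.sentence_index,
        labels=labels,
        reasons=reasons,
        evidence=evidence,
    )


def classify_note(
    sentences: Sequence[Sentence],
    lex: LexiconSet,
    config: RuleConfig | None = None,
) -> tuple[list[SentenceLabelSet], NoteLabelSet]:
    """Label all sentences of one note and aggregate to the note level."""
    config = config or RuleConfig()
    note_excluded = False
    if config.context_scope == "note":
        note_excluded = any(
            c.category == "exclusion_context"
            for s in sentences
            for c in find_cues(s, lex)
        )
    sentence_labels = [
        classify_sentence(s, lex, config, note_context_excluded=note_excluded)
        for s in sentences
    ]
    return sentence_labels, aggregate_note(
        sentence_labels, note_id=sentences[0].note_id if sentences else ""
    )


def aggregate_note(
    sentence_labels: Sequence[SentenceLabelSet], note_id: str | None = None
) -> NoteLabelSet:
    """Note label = Yes iff at least one sentence label is Yes (per symptom).

    An empty note aggregates to No for every symptom.
    """
    if note_id is None:
        if not sentence_labels:
            raise ValueError("note_id required for an empty sentence set")
        note_id = sentence_labels[0].note_id
    if any(sl.note_id != note_id for sl in sentence_labels):
        raise ValueError("sentence labels from different notes")
    labels = {
        sym: YES if any(sl.labels[sym] == YES for sl in sentence_labels) else NO
        for sym in SYMPTOMS
    }
    return NoteLabelSet(note_id=note_id, labels=labels)


def sentence_prediction_records(
    sentence_labels: Iterable[SentenceLabelSet],
) -> list[SentencePrediction]:
    return [
        SentencePrediction(
            note_id=sl.note_id,
            sentence_index=sl.sentence_index,
            symptom=sym,
            label=sl.labels[sym],
            reason=sl.reasons[sym],
            evidence=sl.evidence.get(sym, ""),
        )
        for sl in sentence_labels
        for sym in SYMPTOMS
    ]


def note_prediction_records(
    note_labels: Iterable[NoteLabelSet],
) -> list[NotePrediction]:
    return [NotePrediction(note_id=nl.note_id, labels=dict(nl.labels)) for nl in note_labels]
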