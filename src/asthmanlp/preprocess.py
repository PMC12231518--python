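"""Note preprocessing: normalization, sentence/clause segmentation, section
detection, tokenization, and abbreviation/misspelling standardization.

The pipeline runs in a fixed order — lowercase + character whitelist,
sentence splitting, section detection, tokenization, then term
standardization — and is deterministic and idempotent for a fixed
configuration.

Tokenization splits commas, semicolons and terminal punctuation into their
own tokens, so a ``Sentence``'s ``text`` is the space-joined token stream
(the detokenized, normalized form), which keeps the tokens-rejoin-to-text
invariant exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import ClinicalNote

# Characters retained by normalization, besides lowercase letters and digits.
_KEEP_PUNCT = ".,?;"
_NORMALIZE_RE = re.compile(r"[^a-z0-9 .,?;]")
_WS_RE = re.compile(r"\s+")

#: Tokens that end with a period but never end a sentence.
DEFAULT_GUARD_ABBREVS = frozenset(
    {"dr.", "mr.", "mrs.", "ms.", "st.", "mg.", "ml.", "vs.", "approx."}
)

#: Section header phrases -> canonical section label. Headers are matched as
#: whole clauses; the labels cover the sections symptoms commonly live in.
DEFAULT_HEADER_PATTERNS: tuple[tuple[str, str], ...] = (
    ("chief complaint", "chief_complaint"),
    ("cc", "chief_complaint"),
    ("history of present illness", "hpi"),
    ("hpi", "hpi"),
    ("past medical history", "past_medical_history"),
    ("pmh", "past_medical_history"),
    ("review of systems", "ros"),
    ("ros", "ros"),
    ("problem list", "problem_list"),
    ("medications", "medications"),
    ("current medications", "medications"),
    ("allergies", "allergies"),
    ("questionnaire", "questionnaire"),
    ("symptom checklist", "questionnaire"),
    ("assessment", "assessment"),
    ("assessment and plan", "assessment"),
    ("plan", "plan"),
    ("instructions", "instructions"),
    ("patient instructions", "instructions"),
    ("physical exam", "physical_exam"),
)


class LexiconValidationError(ValueError):
    pass


@dataclass(frozen=True)
class AbbrevMap:
    """Whole-token abbreviation -> expansion map.

    Keys are lowercase and may span a short multi-token phrase; expansions
    never contain a key (acyclic), so single-pass expansion is stable.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        keys = set(self.mapping)
        for key, expansion in self.mapping.items():
            if key != key.lower():
                raise LexiconValidationError(f"abbreviation key not lowercase: {key!r}")
            if key == expansion:
                raise LexiconValidationError(f"abbreviation maps to itself: {key!r}")
            for tok in expansion.split():
                if tok in keys:
                    raise LexiconValidationError(
                        f"expansion of {key!r} contains abbreviation key {tok!r}"
                    )

    def items_longest_first(self) -> list[tuple[tuple[str, ...], list[str]]]:
        pairs = [(tuple(k.split()), v.split()) for k, v in self.mapping.items()]
        return sorted(pairs, key=lambda kv: (-len(kv[0]), kv[0]))


@dataclass(frozen=True)
class Sentence:
    """A preprocessed sentence: tokens, clause structure, and section tag."""

    note_id: str
    sentence_index: int
    tokens: tuple[str, ...]
    section: str = "body"
    clause_boundaries: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if list(self.clause_boundaries) != sorted(set(self.clause_boundaries)):
            raise ValueError("clause_boundaries must be strictly increasing")
        if self.clause_boundaries and self.clause_boundaries[-1] >= len(self.tokens):
            raise ValueError("clause boundary outside token range")

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


@dataclass(frozen=True)
class PreprocessConfig:
    abbrev: AbbrevMap
    vocab: frozenset[str]
    correction_targets: frozenset[str]
    header_patterns: tuple[tuple[str, str], ...] = DEFAULT_HEADER_PATTERNS
    guard_abbrevs: frozenset[str] = DEFAULT_GUARD_ABBREVS


def normalize_text(raw: str) -> str:
    """Lowercase and strip every character outside the whitelist.

    The whitelist is lowercase letters, digits, space, period, comma,
    question mark, and semicolon; anything else becomes a space and runs of
    whitespace collapse.  Idempotent.
    """
    text = _WS_RE.sub(" ", raw.lower())
    text = _NORMALIZE_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def split_sentences(
    text: str, guard_abbrevs: Iterable[str] = DEFAULT_GUARD_ABBREVS
) -> list[str]:
    """Split normalized text at periods/question marks followed by space or end.

    Semicolons and commas stay inside the sentence (they delimit clauses,
    not sentences).  A guard list of dotted abbreviations ("dr.", "mg.")
    suppresses false splits.
    """
    guard = frozenset(guard_abbrevs)
    sentences: list[str] = []
    start = 0
    for i, ch in enumerate(text):
        if ch not in ".?":
            continue
        if i + 1 < len(text) and text[i + 1] != " ":
            continue
        word_start = text.rfind(" ", start, i) + 1
        if text[word_start : i + 1] in guard:
            continue
        chunk = text[start : i + 1].strip()
        if chunk:
            sentences.append(chunk)
        start = i + 1
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def tokenize(sentence_text: str) -> tuple[str, ...]:
    """Whitespace tokenization with trailing punctuation split off as tokens."""
    tokens: list[str] = []
    for chunk in sentence_text.split():
        core = chunk.rstrip(_KEEP_PUNCT)
        trailing = chunk[len(core) :]
        if core:
            tokens.append(core)
        tokens.extend(trailing)
    return tuple(tokens)


def clause_boundaries(tokens: Sequence[str]) -> tuple[int, ...]:
    """Indices of clause-splitting tokens (commas and semicolons)."""
    return tuple(i for i, t in enumerate(tokens) if t in {",", ";"})


def _clauses_of(sentence_text: str) -> list[str]:
    return [c.strip(" .?") for c in re.split(r"[,;]", sentence_text)]


def detect_section(
    sentence_texts: Sequence[str],
    header_patterns: Sequence[tuple[str, str]] = DEFAULT_HEADER_PATTERNS,
) -> list[str]:
    """Label each sentence with the most recent section header at or before it.

    A header is a clause that consists of exactly a header phrase.  The
    header sentence itself carries its own section label; sentences before
    any header are labeled ``"body"``.
    """
    header_map = {phrase: label for phrase, label in header_patterns}
    current = "body"
    labels: list[str] = []
    for text in sentence_texts:
        clauses = _clauses_of(text)
        if clauses and clauses[0] in header_map:
            current = header_map[clauses[0]]
        labels.append(current)
        for clause in clauses[1:]:
            if clause in header_map:
                current = header_map[clause]
    return labels


def _within_edit_distance_1(a: str, b: str) -> bool:
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:  # one substitution
        return sum(x != y for x, y in zip(a, b)) == 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # one insertion into a
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


def standardize_terms(
    tokens: Sequence[str],
    abbrev: AbbrevMap,
    vocab: Iterable[str],
    correction_targets: Iterable[str] | None = None,
) -> tuple[str, ...]:
    """Expand abbreviations and correct near-miss spellings of symptom terms.

    Abbreviation keys are replaced whole-token, left to right, longest key
    first, in a single pass (expansions are not re-scanned).  A token absent
    from ``vocab`` is replaced when it sits at edit distance 1 of exactly
    one word in ``correction_targets`` (default: the vocabulary itself);
    everything else passes through unchanged.
    """
    vocab = frozenset(vocab)
    targets = frozenset(correction_targets) if correction_targets is not None else vocab
    keyed = abbrev.items_longest_first()

    expanded: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        for key_toks, exp_toks in keyed:
            k = len(key_toks)
            if tuple(tokens[i : i + k]) == key_toks:
                expanded.extend(exp_toks)
                i += k
                break
        else:
            expanded.append(tokens[i])
            i += 1

    out: list[str] = []
    for tok in expanded:
        if tok in vocab or not tok.isalpha():
            out.append(tok)
            continue
        hits = [t for t in targets if _within_edit_distance_1(tok, t)]
        out.append(hits[0] if len(hits) == 1 else tok)
    return tuple(out)


def preprocess_note(note: ClinicalNote, config: PreprocessConfig) -> list[Sentence]:
    """Run the full preprocessing pipeline on one note."""
    normalized = normalize_text(note.text)
    texts = split_sentences(normalized, config.guard_abbrevs)
    sections = detect_section(texts, config.header_patterns)
    sentences: list[Sentence] = []
    for idx, (text, section) in enumerate(zip(texts, sections)):
        tokens = standardize_terms(
            tokenize(text), config.abbrev, config.vocab, config.correction_targets
        )
        sentences.append(
            Sentence(
                note_id=note.note_id,
                sentence_index=idx,
                tokens=tokens,
                section=section,
                clause_boundaries=clause_boundaries(tokens),
            )
        )
    return sentences


def _data_path(name: str):
    return resources.files("asthmanlp").joinpath("data", name)


def load_abbrev_map(path: str | Path | None = None) -> AbbrevMap:
    """Load a two-column (tab-separated) abbreviation file."""
    source = Path(path) if path is not None else _data_path("lexicons/abbreviations.tsv")
    mapping: dict[str, str] = {}
    for line in source.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, expansion = line.partition("\t")
        mapping[key.strip()] = expansion.strip()
    return AbbrevMap(mapping)


def load_wordlist(path: str | Path | None = None, name: str = "known_words.txt") -> frozenset[str]:
    source = Path(path) if path is not None else _data_path(name)
    words = set()
    for line in source.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def default_config() -> PreprocessConfig:
    """The shipped preprocessing configuration (editable data files)."""
    from .lexicon import load_lexicons  # deferred: lexicon imports this module

    abbrev = load_abbrev_map()
    lex = load_lexicons()
    targets = set(lex.symptom_vocabulary())
    vocab = set(load_wordlist()) | targets
    for expansion in abbrev.mapping.values():
        vocab.update(expansion.split())
    return PreprocessConfig(
        abbrev=abbrev,
        vocab=frozenset(vocab),
        correction_targets=frozenset(targets),
    )
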