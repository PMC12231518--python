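"""Symptom and context-cue lexicons, plus embedding-based term enrichment.

Every term list is a plain, editable text file: one file per symptom and one
per cue category.  The cue categories drive the rule engine's scoping logic:

* ``negated`` — "no", "denied", "negative for", …
* ``uncertain`` — "likely", "possible", …
* ``definite`` — "positive for", "confirmed", …
* ``history`` — "history of", "a couple of months before", …
* ``nonpatient`` — family members / other persons
* ``general_description`` — templated warning language ("please return if …")
* ``exclusion_context`` — terms (anxiety) that suppress symptom attribution

Term curation was, in the workflow this package supports, an iterative human
process; ``train_embedding`` + ``nearest_terms`` provide the distributional
neighbor lookup used to surface candidate synonyms and misspellings for that
curation.  The embedding is a skip-gram negative-sampling model trained with
a seeded generator, so results are exactly reproducible.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .corpus_io import SYMPTOMS
from .preprocess import LexiconValidationError, normalize_text

CUE_CATEGORIES = (
    "negated",
    "uncertain",
    "definite",
    "history",
    "nonpatient",
    "general_description",
    "exclusion_context",
)


@dataclass(frozen=True)
class ProximityRule:
    """Two anchor token sets that co-occur within a bounded word gap.

    A mention fires when a token from each set appears, in either order,
    with at most ``max_gap`` intervening (non-punctuation) words.  The
    shipped chest-tightness rule allows at most 3 words between a
    tight/tightness token and "chest".
    """

    anchors_a: frozenset[str]
    anchors_b: frozenset[str]
    max_gap: int = 3


@dataclass(frozen=True)
class LexiconSet:
    symptom_terms: Mapping[str, tuple[str, ...]]
    cue_terms: Mapping[str, tuple[str, ...]]
    proximity_rules: Mapping[str, ProximityRule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.symptom_terms) != set(SYMPTOMS):
            raise LexiconValidationError(
                f"symptom keys must be exactly {set(SYMPTOMS)}"
            )
        if set(self.cue_terms) != set(CUE_CATEGORIES):
            raise LexiconValidationError(
                f"cue categories must be exactly {set(CUE_CATEGORIES)}"
            )
        for group in (self.symptom_terms, self.cue_terms):
            for key, phrases in group.items():
                for phrase in phrases:
                    if not phrase or normalize_text(phrase) != phrase:
                        raise LexiconValidationError(
                            f"phrase not normalized in {key!r}: {phrase!r}"
                        )
        seen: dict[str, str] = {}
        for cat, phrases in self.cue_terms.items():
            for phrase in phrases:
                if phrase in seen:
                    raise LexiconValidationError(
                        f"cue phrase {phrase!r} in both {seen[phrase]!r} and {cat!r}"
                    )
                seen[phrase] = cat

    def symptom_vocabulary(self) -> frozenset[str]:
        """Every token occurring in a symptom phrase or proximity anchor."""
        words: set[str] = set()
        for phrases in self.symptom_terms.values():
            for phrase in phrases:
                words.update(phrase.split())
        for rule in self.proximity_rules.values():
            words.update(rule.anchors_a)
            words.update(rule.anchors_b)
        return frozenset(words)


def _default_dir():
    return resources.files("asthmanlp").joinpath("data", "lexicons")


def _read_phrases(source) -> tuple[str, ...]:
    phrases = []
    for line in source.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            phrases.append(line)
    return tuple(phrases)


def load_lexicons(path: str | Path | None = None) -> LexiconSet:
    """Load and validate a lexicon directory (shipped defaults when None)."""
    root = Path(path) if path is not None else _default_dir()
    symptom_terms = {
        sym: _read_phrases(root.joinpath(f"symptom_{sym}.txt")) for sym in SYMPTOMS
    }
    cue_terms = {
        cat: _read_phrases(root.joinpath(f"cue_{cat}.txt")) for cat in CUE_CATEGORIES
    }
    prox_raw = yaml.safe_load(root.joinpath("proximity.yaml").read_text(encoding="utf-8")) or {}
    proximity = {
        sym: ProximityRule(
            anchors_a=frozenset(rule["anchors_a"]),
            anchors_b=frozenset(rule["anchors_b"]),
            max_gap=int(rule.get("max_gap", 3)),
        )
        for sym, rule in prox_raw.items()
    }
    return LexiconSet(symptom_terms=symptom_terms, cue_terms=cue_terms, proximity_rules=proximity)


def save_lexicons(lex: LexiconSet, path: str | Path) -> None:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for sym, phrases in lex.symptom_terms.items():
        (root / f"symptom_{sym}.txt").write_text("\n".join(phrases) + "\n", encoding="utf-8")
    for cat, phrases in lex.cue_terms.items():
        (root / f"cue_{cat}.txt").write_text(
            ("\n".join(phrases) + "\n") if phrases else "", encoding="utf-8"
        )
    prox = {
        sym: {
            "anchors_a": sorted(rule.anchors_a),
            "anchors_b": sorted(rule.anchors_b),
            "max_gap": rule.max_gap,
        }
        for sym, rule in lex.proximity_rules.items()
    }
    (root / "proximity.yaml").write_text(yaml.safe_dump(prox), encoding="utf-8")


# ---------------------------------------------------------------------------
# Distributional embeddings (skip-gram with negative sampling)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbeddingModel:
    vocabulary: tuple[str, ...]
    vectors: np.ndarray  # (V, dim)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("one vector per vocabulary word required")

    @property
    def dimension(self) -> int:
        return int(self.vectors.shape[1])

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.vocabulary.index(word)]


def nearest_terms(model: EmbeddingModel, query: str, k: int) -> list[str]:
    """The ``k`` vocabulary words most cosine-similar to ``query``.

    The query itself is excluded; ties break lexicographically.  Raises
    ``KeyError`` for an out-of-vocabulary query.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if query not in model.vocabulary:
        raise KeyError(f"query {query!r} not in vocabulary")
    qi = model.vocabulary.index(query)
    vecs = model.vectors
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    sims = (vecs @ vecs[qi]) / (norms * max(norms[qi], 1e-12))
    order = sorted(
        (w for i, w in enumerate(model.vocabulary) if i != qi),
        key=lambda w: (-sims[model.vocabulary.index(w)], w),
    )
    return order[:k]


def train_embedding(
    sentences: Sequence[Sequence[str]],
    dimension: int = 50,
    window: int = 5,
    epochs: int = 50,
    seed: int = 0,
    min_count: int = 2,
    negative: int = 5,
    learning_rate: float = 0.025,
) -> EmbeddingModel:
    """Train a skip-gram negative-sampling word embedding on token sequences.

    Single-threaded and fully seeded, so two runs with the same arguments
    produce identical vectors.  Vocabulary keeps tokens with frequency >=
    ``min_count``, ordered by descending frequency then alphabetically.
    Negative samples are drawn from the unigram distribution raised to 3/4.
    """
    sentences = [list(s) for s in sentences if len(s) > 0]
    if not sentences:
        raise ValueError("empty corpus")
    freq: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            freq[tok] = freq.get(tok, 0) + 1
    vocab = tuple(
        sorted((w for w, c in freq.items() if c >= min_count), key=lambda w: (-freq[w], w))
    )
    if not vocab:
        raise ValueError("no token reaches min_count; corpus too small")
    index = {w: i for i, w in enumerate(vocab)}

    centers: list[int] = []
    contexts: list[int] = []
    for sent in sentences:
        ids = [index[t] for t in sent if t in index]
        for pos, c in enumerate(ids):
            lo = max(0, pos - window)
            hi = min(len(ids), pos + window + 1)
            for other in range(lo, hi):
                if other != pos:
                    centers.append(c)
                    contexts.append(ids[other])
    if not centers:
        raise ValueError("corpus yields no training pairs")
    centers_arr = np.asarray(centers, dtype=np.int64)
    contexts_arr = np.asarray(contexts, dtype=np.int64)

    rng = np.random.default_rng(seed)
    V = len(vocab)
    W = (rng.random((V, dimension)) - 0.5) / dimension  # input vectors
    U = np.zeros((V, dimension))  # output vectors

    counts = np.array([freq[w] for w in vocab], dtype=np.float64)
    noise = counts**0.75
    noise /= noise.sum()

    from scipy.special import expit

    n_pairs = len(centers_arr)
    batch = min(64, n_pairs)
    total_steps = epochs * math.ceil(n_pairs / batch)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            # linearly decaying step size, the usual SGNS schedule
            lr = learning_rate * max(1.0 - step / total_steps, 1e-4)
            step += 1
            sel = order[start : start + batch]
            c = centers_arr[sel]
            o = contexts_arr[sel]
            neg = rng.choice(V, size=(len(sel), negative), p=noise)

            wc = W[c]  # (b, d)
            uo = U[o]
            un = U[neg]  # (b, k, d)

            pos_score = expit(np.einsum("bd,bd->b", wc, uo))
            neg_score = expit(np.einsum("bd,bkd->bk", wc, un))

            g_pos = (pos_score - 1.0)[:, None]  # (b, 1)
            g_neg = neg_score[:, :, None]  # (b, k, 1)

            grad_wc = g_pos * uo + np.einsum("bko,bkd->bd", g_neg, un)
            grad_uo = g_pos * wc
            grad_un = g_neg * wc[:, None, :]

            np.add.at(W, c, -lr * np.clip(grad_wc, -1.0, 1.0))
            np.add.at(U, o, -lr * np.clip(grad_uo, -1.0, 1.0))
            np.add.at(
                U, neg.ravel(), -lr * np.clip(grad_un, -1.0, 1.0).reshape(-1, dimension)
            )

    return EmbeddingModel(vocabulary=vocab, vectors=W)
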