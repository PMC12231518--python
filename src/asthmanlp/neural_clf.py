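"""Transformer sentence classifier with masked-language-model pretraining.

A compact BERT-style encoder — learned word + position embeddings, pre-norm
multi-head self-attention blocks, GELU feed-forward layers — written
directly in numpy with hand-derived gradients and an Adam optimizer, so the
whole train/predict cycle is single-threaded, CPU-friendly and exactly
reproducible from a seed.  Pretraining masks a configurable fraction of the
tokens of each sentence (default 20%, using the usual mask/random/keep
split) and predicts them; per-symptom fine-tuning attaches an independent
sigmoid head to the [CLS] position and trains through the encoder with
5-fold cross-training-validation, folds assigned by note so sentences from
one note never straddle the train/validation boundary.

The desk default configuration (64-dim, 2 layers, 2 heads, 128-token
sequences, batch 16, lr 1e-4) trains on synthetic corpora in seconds to
minutes on one CPU; ``FULL_SCALE_CONFIG`` carries the full-scale settings
(512-token sequences, lr 1e-5, batch 32) used when real GPU-scale training
is available.

Downstream code only requires the ``predict_proba`` contract, so any
probabilistic sentence classifier can stand in; ``BowLogisticClassifier``
is a bag-of-words logistic stub for fast tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import NO, YES

PAD, UNK, MASK, CLS = "[PAD]", "[UNK]", "[MASK]", "[CLS]"
_SPECIALS = (PAD, UNK, MASK, CLS)


@dataclass(frozen=True)
class NeuralConfig:
    max_sequence_length: int = 128
    learning_rate: float = 1e-4
    batch_size: int = 16
    mlm_mask_fraction: float = 0.20
    mask_token_prob: float = 0.8  # of selected positions: replaced by [MASK]
    random_token_prob: float = 0.1  # ... replaced by a random word
    hidden_dimension: int = 64
    layer_count: int = 2
    head_count: int = 2
    pretrain_epochs: int = 30
    finetune_epochs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mlm_mask_fraction < 1.0:
            raise ValueError("mlm_mask_fraction must be in (0, 1)")
        for name in (
            "max_sequence_length",
            "batch_size",
            "hidden_dimension",
            "layer_count",
            "head_count",
            "pretrain_epochs",
            "finetune_epochs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.hidden_dimension % self.head_count:
            raise ValueError("hidden_dimension must be divisible by head_count")


#: Full-scale settings for GPU-scale corpora (512-token sequences, 12x768).
FULL_SCALE_CONFIG = NeuralConfig(
    max_sequence_length=512,
    learning_rate=1e-5,
    batch_size=32,
    hidden_dimension=768,
    layer_count=12,
    head_count=12,
    pretrain_epochs=40,
    finetune_epochs=4,
)


@dataclass(frozen=True)
class ProbabilitySet:
    note_id: str
    sentence_index: int
    probabilities: Mapping[str, float]

    def __post_init__(self) -> None:
        for sym, p in self.probabilities.items():
            if not (np.isfinite(p) and 0.0 <= p <= 1.0):
                raise ValueError(f"probability for {sym} outside [0, 1]: {p}")


@dataclass(frozen=True)
class FoldAssignment:
    """Note-id -> fold-index map; 5 folds whose sizes differ by at most 1."""

    folds: Mapping[str, int]
    n_folds: int = 5

    def __post_init__(self) -> None:
        values = list(self.folds.values())
        if any(not 0 <= v < self.n_folds for v in values):
            raise ValueError("fold index out of range")
        sizes = [values.count(k) for k in range(self.n_folds)]
        if values and max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")


def make_folds(note_ids: Sequence[str], n_folds: int = 5, seed: int = 0) -> FoldAssignment:
    """Randomly assign notes to near-equal folds (all sentences of a note
    share its fold)."""
    unique = sorted(set(note_ids))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    folds = {unique[int(j)]: int(i % n_folds) for i, j in enumerate(order)}
    return FoldAssignment(folds=folds, n_folds=n_folds)


@dataclass(frozen=True)
class Vocab:
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tokens[: len(_SPECIALS)] != _SPECIALS:
            raise ValueError("vocabulary must start with the special symbols")

    @property
    def size(self) -> int:
        return len(self.tokens)

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}


def build_vocab(sentences: Iterable[Sequence[str]], min_frequency: int = 1) -> Vocab:
    """Deterministic vocabulary: specials, then words with frequency >=
    ``min_frequency`` ordered by descending frequency, then alphabetically.
    Rarer tokens map to [UNK] at encoding time."""
    freq: dict[str, int] = {}
    empty = True
    for sent in sentences:
        empty = False
        for tok in sent:
            freq[tok] = freq.get(tok, 0) + 1
    if empty:
        raise ValueError("empty corpus")
    kept = sorted(
        (w for w, c in freq.items() if c >= min_frequency), key=lambda w: (-freq[w], w)
    )
    return Vocab(tokens=_SPECIALS + tuple(kept))


def encode(
    sentences: Sequence[Sequence[str]], vocab: Vocab, max_len: int
) -> np.ndarray:
    """Token-id matrix (n, T) with a leading [CLS], right-padded; sequences
    longer than ``max_len`` are truncated."""
    idx = vocab.index()
    unk, pad = idx[UNK], idx[PAD]
    T = min(max(len(s) for s in sentences) + 1, max_len) if sentences else 1
    out = np.full((len(sentences), T), pad, dtype=np.int64)
    out[:, 0] = idx[CLS]
    for i, sent in enumerate(sentences):
        ids = [idx.get(t, unk) for t in sent][: T - 1]
        out[i, 1 : 1 + len(ids)] = ids
    return out


# ---------------------------------------------------------------------------
# Parameters, forward pass, and hand-derived backward pass
# ---------------------------------------------------------------------------

_LN_EPS = 1e-5


def _init_params(config: NeuralConfig, vocab_size: int, rng: np.random.Generator):
    D = config.hidden_dimension
    F = 4 * D
    scale = 0.02
    p: dict[str, np.ndarray] = {
        "emb": rng.normal(0, scale, (vocab_size, D)),
        "pos": rng.normal(0, scale, (config.max_sequence_length, D)),
        "lnf_g": np.ones(D),
        "lnf_b": np.zeros(D),
        "mlm_w": rng.normal(0, scale, (D, vocab_size)),
        "mlm_b": np.zeros(vocab_size),
    }
    for l in range(config.layer_count):
        p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"] = np.ones(D), np.zeros(D)
        p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"] = np.ones(D), np.zeros(D)
        for name in ("wq", "wk", "wv", "wo"):
            p[f"l{l}_{name}"] = rng.normal(0, scale, (D, D))
        p[f"l{l}_bq"], p[f"l{l}_bk"] = np.zeros(D), np.zeros(D)
        p[f"l{l}_bv"], p[f"l{l}_bo"] = np.zeros(D), np.zeros(D)
        p[f"l{l}_w1"] = rng.normal(0, scale, (D, F))
        p[f"l{l}_b1"] = np.zeros(F)
        p[f"l{l}_w2"] = rng.normal(0, scale, (F, D))
        p[f"l{l}_b2"] = np.zeros(D)
    return p


def _layernorm(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv)


def _layernorm_backward(dy, g, cache):
    xhat, inv = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


_GELU_C = math.sqrt(2.0 / math.pi)


def _gelu(x):
    inner = _GELU_C * (x + 0.044715 * x**3)
    return 0.5 * x * (1.0 + np.tanh(inner))


def _gelu_grad(x):
    inner = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * _GELU_C * (1.0 + 3 * 0.044715 * x**2)


def _split_heads(x, H):
    B, T, D = x.shape
    return x.reshape(B, T, H, D // H).transpose(0, 2, 1, 3)  # (B,H,T,dh)


def _merge_heads(x):
    B, H, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)


def _forward(params, ids, config: NeuralConfig):
    """Encoder forward pass; returns final hidden states and a cache for
    backprop."""
    H = config.head_count
    B, T = ids.shape
    pad_mask = ids == 0  # (B, T) True at padding
    h = params["emb"][ids] + params["pos"][:T]
    key_bias = np.where(pad_mask[:, None, None, :], -1e9, 0.0)  # (B,1,1,T)

    caches = []
    for l in range(config.layer_count):
        pre = h
        a, ln1c = _layernorm(h, params[f"l{l}_ln1_g"], params[f"l{l}_ln1_b"])
        q = _split_heads(a @ params[f"l{l}_wq"] + params[f"l{l}_bq"], H)
        k = _split_heads(a @ params[f"l{l}_wk"] + params[f"l{l}_bk"], H)
        v = _split_heads(a @ params[f"l{l}_wv"] + params[f"l{l}_bv"], H)
        dh = q.shape[-1]
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(dh) + key_bias
        scores -= scores.max(-1, keepdims=True)
        e = np.exp(scores)
        att = e / e.sum(-1, keepdims=True)  # (B,H,T,T)
        ctx = _merge_heads(att @ v)
        o = ctx @ params[f"l{l}_wo"] + params[f"l{l}_bo"]
        h = pre + o

        pre2 = h
        b2, ln2c = _layernorm(h, params[f"l{l}_ln2_g"], params[f"l{l}_ln2_b"])
        u = b2 @ params[f"l{l}_w1"] + params[f"l{l}_b1"]
        gu = _gelu(u)
        f = gu @ params[f"l{l}_w2"] + params[f"l{l}_b2"]
        h = pre2 + f
        caches.append((a, ln1c, q, k, v, att, ctx, b2, ln2c, u, gu))

    out, lnfc = _layernorm(h, params["lnf_g"], params["lnf_b"])
    return out, (ids, pad_mask, caches, lnfc, h)


def _backward(params, dout, cache, config: NeuralConfig):
    """Gradient of a scalar loss wrt every parameter, given d(loss)/d(out)."""
    ids, pad_mask, caches, lnfc, h_last = cache
    H = config.head_count
    B, T = ids.shape
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    dh, dg, db = _layernorm_backward(dout, params["lnf_g"], lnfc)
    grads["lnf_g"] += dg
    grads["lnf_b"] += db

    for l in range(config.layer_count - 1, -1, -1):
        a, ln1c, q, k, v, att, ctx, b2, ln2c, u, gu = caches[l]
        # feed-forward block
        df = dh
        grads[f"l{l}_w2"] += gu.reshape(-1, gu.shape[-1]).T @ df.reshape(-1, df.shape[-1])
        grads[f"l{l}_b2"] += df.sum((0, 1))
        dgu = df @ params[f"l{l}_w2"].T
        du = dgu * _gelu_grad(u)
        grads[f"l{l}_w1"] += b2.reshape(-1, b2.shape[-1]).T @ du.reshape(-1, du.shape[-1])
        grads[f"l{l}_b1"] += du.sum((0, 1))
        db2 = du @ params[f"l{l}_w1"].T
        dpre2, dg2, dbb2 = _layernorm_backward(db2, params[f"l{l}_ln2_g"], ln2c)
        grads[f"l{l}_ln2_g"] += dg2
        grads[f"l{l}_ln2_b"] += dbb2
        dh = dh + dpre2  # residual

        # attention block
        do = dh
        grads[f"l{l}_wo"] += ctx.reshape(-1, ctx.shape[-1]).T @ do.reshape(-1, do.shape[-1])
        grads[f"l{l}_bo"] += do.sum((0, 1))
        dctx = _split_heads(do @ params[f"l{l}_wo"].T, H)
        datt = dctx @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ dctx
        dscores = att * (datt - (datt * att).sum(-1, keepdims=True))
        dhd = q.shape[-1]
        dq = dscores @ k / math.sqrt(dhd)
        dk = dscores.transpose(0, 1, 3, 2) @ q / math.sqrt(dhd)
        dqm, dkm, dvm = _merge_heads(dq), _merge_heads(dk), _merge_heads(dv)
        a2 = a.reshape(-1, a.shape[-1])
        grads[f"l{l}_wq"] += a2.T @ dqm.reshape(-1, dqm.shape[-1])
        grads[f"l{l}_wk"] += a2.T @ dkm.reshape(-1, dkm.shape[-1])
        grads[f"l{l}_wv"] += a2.T @ dvm.reshape(-1, dvm.shape[-1])
        grads[f"l{l}_bq"] += dqm.sum((0, 1))
        grads[f"l{l}_bk"] += dkm.sum((0, 1))
        grads[f"l{l}_bv"] += dvm.sum((0, 1))
        da = (
            dqm @ params[f"l{l}_wq"].T
            + dkm @ params[f"l{l}_wk"].T
            + dvm @ params[f"l{l}_wv"].T
        )
        dpre, dg1, dbb1 = _layernorm_backward(da, params[f"l{l}_ln1_g"], ln1c)
        grads[f"l{l}_ln1_g"] += dg1
        grads[f"l{l}_ln1_b"] += dbb1
        dh = dh + dpre

    np.add.at(grads["emb"], ids, dh)
    grads["pos"][:T] += dh.sum(0)
    return grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Pretraining
# ---------------------------------------------------------------------------


@dataclass
class EncoderState:
    params: dict[str, np.ndarray]
    vocab: Vocab
    config: NeuralConfig
    mlm_losses: list[float] = field(default_factory=list)


def mask_tokens(
    ids: np.ndarray,
    vocab: Vocab,
    config: NeuralConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Select exactly round(fraction * n_real) positions per sequence.

    Returns (corrupted ids, target ids) where targets are -1 except at
    selected positions.  Selected positions become [MASK] with probability
    ``mask_token_prob``, a random non-special token with
    ``random_token_prob``, and stay unchanged otherwise.
    """
    idx = vocab.index()
    corrupted = ids.copy()
    targets = np.full_like(ids, -1)
    n_words = vocab.size - len(_SPECIALS)
    for i in range(ids.shape[0]):
        real = np.where((ids[i] != idx[PAD]) & (ids[i] != idx[CLS]))[0]
        n_mask = int(round(config.mlm_mask_fraction * len(real)))
        if n_mask == 0 and len(real) > 0:
            n_mask = 1
        chosen = rng.choice(real, size=n_mask, replace=False)
        targets[i, chosen] = ids[i, chosen]
        for j in chosen:
            r = rng.random()
            if r < config.mask_token_prob:
                corrupted[i, j] = idx[MASK]
            elif r < config.mask_token_prob + config.random_token_prob and n_words > 0:
                corrupted[i, j] = len(_SPECIALS) + int(rng.integers(n_words))
    return corrupted, targets


def _mlm_loss_and_grad(params, ids_corrupt, targets, config):
    out, cache = _forward(params, ids_corrupt, config)
    logits = out @ params["mlm_w"] + params["mlm_b"]  # (B,T,V)
    sel = targets >= 0
    if not sel.any():
        raise ValueError("no masked positions")
    z = logits[sel]  # (M,V)
    y = targets[sel]
    z = z - z.max(-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(-1, keepdims=True))
    loss = -logp[np.arange(len(y)), y].mean()

    dlogits_sel = np.exp(logp)
    dlogits_sel[np.arange(len(y)), y] -= 1.0
    dlogits_sel /= len(y)
    dlogits = np.zeros_like(logits)
    dlogits[sel] = dlogits_sel

    dout = dlogits @ params["mlm_w"].T
    grads = _backward(params, dout, cache, config)
    grads["mlm_w"] += out.reshape(-1, out.shape[-1]).T @ dlogits.reshape(-1, dlogits.shape[-1])
    grads["mlm_b"] += dlogits.sum((0, 1))
    return loss, grads


def mlm_pretrain(
    sentences: Sequence[Sequence[str]],
    config: NeuralConfig,
    vocab: Vocab | None = None,
) -> EncoderState:
    """Masked-language-model pretraining on tokenized sentences.

    Records the mean masked-token cross-entropy per epoch in
    ``mlm_losses``.  Sequences beyond ``max_sequence_length`` are truncated.
    """
    sentences = [list(s) for s in sentences if s]
    if not sentences:
        raise ValueError("empty corpus")
    vocab = vocab or build_vocab(sentences)
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, vocab.size, rng)
    opt = _Adam(params, config.learning_rate)
    ids_all = encode(sentences, vocab, config.max_sequence_length)

    losses = []
    n = len(sentences)
    for _ in range(config.pretrain_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch = ids_all[order[start : start + config.batch_size]]
            corrupted, targets = mask_tokens(batch, vocab, config, rng)
            loss, grads = _mlm_loss_and_grad(params, corrupted, targets, config)
            opt.step(params, grads)
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    return EncoderState(params=params, vocab=vocab, config=config, mlm_losses=losses)


# ---------------------------------------------------------------------------
# Fine-tuning and prediction
# ---------------------------------------------------------------------------


@dataclass
class ClassifierState:
    params: dict[str, np.ndarray]  # encoder + "cls_w", "cls_b"
    vocab: Vocab
    config: NeuralConfig
    symptom: str = ""
    fold_aucs: list[float | None] = field(default_factory=list)


def _clf_loss_and_grad(params, ids, y, config):
    out, cache = _forward(params, ids, config)
    z = out[:, 0]  # [CLS]
    logit = z @ params["cls_w"] + params["cls_b"]
    p = 1.0 / (1.0 + np.exp(-logit))
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    dlogit = (p - y) / len(y)
    dz = np.outer(dlogit, params["cls_w"])
    dout = np.zeros_like(out)
    dout[:, 0] = dz
    grads = _backward(
        {k: v for k, v in params.items() if not k.startswith("cls_")}, dout, cache, config
    )
    grads["cls_w"] = z.T @ dlogit
    grads["cls_b"] = np.array(dlogit.sum())
    return loss, grads


def _train_classifier(encoder_params, vocab, config, ids, y, rng):
    params = {k: v.copy() for k, v in encoder_params.items()}
    D = config.hidden_dimension
    params["cls_w"] = rng.normal(0, 0.02, D)
    params["cls_b"] = np.array(0.0)
    opt = _Adam(params, config.learning_rate)
    n = len(y)
    for _ in range(config.finetune_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            _, grads = _clf_loss_and_grad(params, ids[sel], y[sel], config)
            opt.step(params, grads)
    return params


def _predict_ids(params, ids, config, batch_size=64):
    probs = []
    for start in range(0, len(ids), batch_size):
        out, _ = _forward(params, ids[start : start + batch_size], config)
        logit = out[:, 0] @ params["cls_w"] + params["cls_b"]
        probs.append(1.0 / (1.0 + np.exp(-logit)))
    return np.concatenate(probs) if probs else np.empty(0)


def finetune_symptom(
    encoder: EncoderState,
    sentences: Sequence[Sequence[str]],
    labels: Sequence[str],
    note_ids: Sequence[str],
    folds: FoldAssignment,
    symptom: str = "",
) -> tuple[ClassifierState, list[float | None]]:
    """Per-symptom fine-tuning with cross-training-validation.

    For each fold, trains on the other folds and reports AUC on the held-out
    fold (None when the fold holds a single class); the returned final model
    is refit on all data.  Deterministic for a fixed encoder config seed.
    """
    from .hybrid_eval import roc_auc

    if any(l not in (YES, NO) for l in labels):
        raise ValueError("labels must be Yes/No")
    config, vocab = encoder.config, encoder.vocab
    ids = encode([list(s) for s in sentences], vocab, config.max_sequence_length)
    y = np.array([1.0 if l == YES else 0.0 for l in labels])
    fold_of = np.array([folds.folds[nid] for nid in note_ids])

    fold_aucs: list[float | None] = []
    for k in range(folds.n_folds):
        rng = np.random.default_rng(config.seed + 1000 + k)
        train_sel = fold_of != k
        val_sel = ~train_sel
        params = _train_classifier(
            encoder.params, vocab, config, ids[train_sel], y[train_sel], rng
        )
        yv = y[val_sel]
        if len(set(yv.tolist())) < 2:
            fold_aucs.append(None)
            continue
        pv = _predict_ids(params, ids[val_sel], config)
        fold_aucs.append(
            roc_auc([YES if v else NO for v in yv], pv.tolist())
        )

    rng = np.random.default_rng(config.seed + 999)
    final_params = _train_classifier(encoder.params, vocab, config, ids, y, rng)
    state = ClassifierState(
        params=final_params, vocab=vocab, config=config, symptom=symptom,
        fold_aucs=fold_aucs,
    )
    return state, fold_aucs


def predict_proba(
    classifier: ClassifierState, sentences: Sequence[Sequence[str]]
) -> np.ndarray:
    """P(symptom present) per sentence, in [0, 1]; empty in, empty out."""
    if not sentences:
        return np.empty(0)
    ids = encode(
        [list(s) for s in sentences], classifier.vocab, classifier.config.max_sequence_length
    )
    return _predict_ids(classifier.params, ids, classifier.config)


def hard_labels(probabilities: Sequence[float]) -> list[str]:
    """Threshold at 0.5: Yes when P >= .5, No when P < .5."""
    return [YES if p >= 0.5 else NO for p in probabilities]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_state(state: EncoderState | ClassifierState, directory: str | Path) -> None:
    """Write weights (npz), vocabulary and config to ``directory``;
    round-trips to bitwise-identical predictions."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **state.params)
    (directory / "vocab.txt").write_text("\n".join(state.vocab.tokens), encoding="utf-8")
    meta = {"config": asdict(state.config), "kind": type(state).__name__}
    if isinstance(state, ClassifierState):
        meta["symptom"] = state.symptom
        meta["fold_aucs"] = state.fold_aucs
    else:
        meta["mlm_losses"] = state.mlm_losses
    (directory / "config.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")


def load_state(directory: str | Path) -> EncoderState | ClassifierState:
    directory = Path(directory)
    with np.load(directory / "weights.npz") as npz:
        params = {k: npz[k] for k in npz.files}
    vocab = Vocab(tuple((directory / "vocab.txt").read_text(encoding="utf-8").split("\n")))
    meta = json.loads((directory / "config.json").read_text(encoding="utf-8"))
    config = NeuralConfig(**meta["config"])
    if meta["kind"] == "ClassifierState":
        return ClassifierState(
            params=params, vocab=vocab, config=config,
            symptom=meta.get("symptom", ""), fold_aucs=meta.get("fold_aucs", []),
        )
    return EncoderState(
        params=params, vocab=vocab, config=config, mlm_losses=meta.get("mlm_losses", [])
    )


# ---------------------------------------------------------------------------
# Bag-of-words stub satisfying the same predict_proba contract
# ---------------------------------------------------------------------------


class BowLogisticClassifier:
    """Binary bag-of-words logistic regression over sentence tokens.

    A fast, fully substitutable stand-in for the transformer classifier in
    downstream hybrid/evaluation code.
    """

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed
        self._model = None
        self._vocab: dict[str, int] = {}

    def _features(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        X = np.zeros((len(sentences), max(len(self._vocab), 1)))
        for i, sent in enumerate(sentences):
            for tok in sent:
                j = self._vocab.get(tok)
                if j is not None:
                    X[i, j] = 1.0
        return X

    def fit(self, sentences: Sequence[Sequence[str]], labels: Sequence[str]):
        from sklearn.linear_model import LogisticRegression

        self._vocab = {
            t: i for i, t in enumerate(sorted({tok for s in sentences for tok in s}))
        }
        y = np.array([1 if l == YES else 0 for l in labels])
        self._model = LogisticRegression(C=self.C, max_iter=1000, random_state=self.seed)
        self._model.fit(self._features(sentences), y)
        return self

    def predict_proba(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        if not sentences:
            return np.empty(0)
        if self._model is None:
            raise RuntimeError("classifier not fitted")
        return self._model.predict_proba(self._features(sentences))[:, 1]
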