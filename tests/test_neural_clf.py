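import numpy as np
import pytest

from asthmanlp.corpus_io import NO, YES
from asthmanlp.neural_clf import (
    BowLogisticClassifier,
    FoldAssignment,
    NeuralConfig,
    Vocab,
    _clf_loss_and_grad,
    _init_params,
    _mlm_loss_and_grad,
    build_vocab,
    encode,
    finetune_symptom,
    hard_labels,
    load_state,
    make_folds,
    mask_tokens,
    mlm_pretrain,
    predict_proba,
    save_state,
)

TINY = NeuralConfig(
    hidden_dimension=32,
    head_count=2,
    layer_count=1,
    max_sequence_length=24,
    batch_size=8,
    learning_rate=1e-3,
    pretrain_epochs=8,
    finetune_epochs=6,
    seed=0,
)

_FILLER = ["visit", "today", "stable", "well", "home", "plan", "rest", "water", "clinic"]


def _marker_corpus(n=120, seed=0):
    """Sentences of filler words; label = presence of the marker token."""
    rng = np.random.default_rng(seed)
    sentences, labels, note_ids = [], [], []
    for i in range(n):
        k = int(rng.integers(3, 8))
        sent = [str(_FILLER[int(j)]) for j in rng.integers(0, len(_FILLER), size=k)]
        if rng.random() < 0.5:
            sent.insert(int(rng.integers(len(sent) + 1)), "wheezing")
            labels.append(YES)
        else:
            labels.append(NO)
        sentences.append(sent)
        note_ids.append(f"n{i % 40}")  # several sentences share a note
    return sentences, labels, note_ids


class TestVocab:
    def test_vocab_contains_words_and_specials(self):
        v = build_vocab([["no", "cough"], ["no", "cough"]], min_frequency=1)
        assert {"no", "cough", "[PAD]", "[MASK]", "[UNK]", "[CLS]"} <= set(v.tokens)

    def test_min_frequency_threshold(self):
        v = build_vocab([["no", "cough"], ["no", "cough"]], min_frequency=3)
        assert "no" not in v.tokens and "cough" not in v.tokens

    def test_deterministic_order(self):
        sents = [["b", "a", "c"], ["a", "c"], ["a"]]
        assert build_vocab(sents).tokens == build_vocab(sents).tokens
        # frequency-descending, alphabetical within ties
        assert build_vocab(sents).tokens[4:] == ("a", "c", "b")

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            build_vocab([])

    def test_encode_truncates_and_pads(self):
        v = build_vocab([["a", "b"]])
        ids = encode([["a"], ["a", "b", "a", "b", "a"]], v, max_len=4)
        assert ids.shape == (2, 4)
        assert ids[0, 0] == v.tokens.index("[CLS]")
        assert ids[0, 2] == 0  # padding


class TestMasking:
    def test_exact_fraction_of_real_tokens_masked(self):
        v = build_vocab([["w"] * 10])
        ids = encode([["w"] * 10], v, max_len=16)
        rng = np.random.default_rng(0)
        cfg = NeuralConfig(mlm_mask_fraction=0.2)
        for _ in range(5):
            _, targets = mask_tokens(ids, v, cfg, rng)
            assert (targets >= 0).sum() == 2  # 20% of 10 tokens

    def test_cls_and_padding_never_masked(self):
        v = build_vocab([["a", "b", "c"]])
        ids = encode([["a", "b", "c"]], v, max_len=8)
        rng = np.random.default_rng(1)
        cfg = NeuralConfig(mlm_mask_fraction=0.5)
        for _ in range(10):
            corrupted, targets = mask_tokens(ids, v, cfg, rng)
            assert targets[0, 0] == -1
            assert (targets[0, 4:] == -1).all()


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences on every
        parameter tensor for both training objectives."""
        cfg = NeuralConfig(
            hidden_dimension=8, head_count=2, layer_count=2, max_sequence_length=10,
            batch_size=4, seed=0,
        )
        rng = np.random.default_rng(0)
        sents = [["no", "cough", "today"], ["patient", "reports", "wheezing"]]
        vocab = build_vocab(sents)
        params = _init_params(cfg, vocab.size, rng)
        ids = encode(sents, vocab, cfg.max_sequence_length)
        corrupted, targets = mask_tokens(ids, vocab, cfg, rng)
        _, grads = _mlm_loss_and_grad(params, corrupted, targets, cfg)
        h = 1e-6
        check_rng = np.random.default_rng(1)
        for name, arr in params.items():
            flat = arr.reshape(-1)
            for idx in check_rng.choice(flat.size, size=min(2, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp, _ = _mlm_loss_and_grad(params, corrupted, targets, cfg)
                flat[idx] = orig - h
                lm, _ = _mlm_loss_and_grad(params, corrupted, targets, cfg)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * h)
                analytic = grads[name].reshape(-1)[idx]
                assert analytic == pytest.approx(numeric, abs=1e-5, rel=1e-4), name

        params["cls_w"] = rng.normal(0, 0.02, cfg.hidden_dimension)
        params["cls_b"] = np.array(0.0)
        y = np.array([1.0, 0.0])
        _, grads = _clf_loss_and_grad(params, ids, y, cfg)
        for name in ("cls_w", "cls_b", "emb", "l0_wq", "l1_w2"):
            flat = params[name].reshape(-1)
            for idx in check_rng.choice(flat.size, size=min(2, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp, _ = _clf_loss_and_grad(params, ids, y, cfg)
                flat[idx] = orig - h
                lm, _ = _clf_loss_and_grad(params, ids, y, cfg)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * h)
                assert grads[name].reshape(-1)[idx] == pytest.approx(
                    numeric, abs=1e-5, rel=1e-4
                ), name


class TestPretraining:
    def test_loss_decreases_on_learnable_corpus(self):
        sentences, _, _ = _marker_corpus(n=80, seed=2)
        state = mlm_pretrain(sentences, TINY)
        assert state.mlm_losses[-1] < state.mlm_losses[0]

    def test_same_seed_reproduces_identical_state(self):
        sentences, _, _ = _marker_corpus(n=40, seed=3)
        cfg = NeuralConfig(**{**TINY.__dict__, "pretrain_epochs": 2})
        a = mlm_pretrain(sentences, cfg)
        b = mlm_pretrain(sentences, cfg)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_serialization_round_trip_identical(self, tmp_path):
        sentences, labels, note_ids = _marker_corpus(n=40, seed=4)
        cfg = NeuralConfig(**{**TINY.__dict__, "pretrain_epochs": 2, "finetune_epochs": 2})
        enc = mlm_pretrain(sentences, cfg)
        folds = make_folds(note_ids, seed=0)
        clf, _ = finetune_symptom(enc, sentences, labels, note_ids, folds, "wheezing")
        before = predict_proba(clf, sentences)
        save_state(clf, tmp_path / "model")
        loaded = load_state(tmp_path / "model")
        after = predict_proba(loaded, sentences)
        np.testing.assert_array_equal(before, after)


class TestFolds:
    def test_every_note_validated_exactly_once(self):
        ids = [f"n{i}" for i in range(100)]
        assignment = make_folds(ids, n_folds=5, seed=1)
        sizes = [list(assignment.folds.values()).count(k) for k in range(5)]
        assert sizes == [20] * 5

    def test_unbalanced_assignment_rejected(self):
        with pytest.raises(ValueError):
            FoldAssignment(folds={"a": 0, "b": 0, "c": 0}, n_folds=2)

    def test_sentences_of_one_note_share_fold(self):
        _, _, note_ids = _marker_corpus(n=60, seed=5)
        assignment = make_folds(note_ids, seed=2)
        by_note = {}
        for nid in note_ids:
            by_note.setdefault(nid, assignment.folds[nid])
            assert assignment.folds[nid] == by_note[nid]


class TestFineTuneAndPredict:
    def test_marker_token_labels_reach_high_cv_auc(self):
        """A linearly separable labeling (marker-token presence) is learned
        to mean internal-validation AUC >= 0.95 at the tiny config."""
        sentences, labels, note_ids = _marker_corpus(n=120, seed=6)
        enc = mlm_pretrain(sentences, TINY)
        folds = make_folds(note_ids, seed=3)
        _, aucs = finetune_symptom(enc, sentences, labels, note_ids, folds, "wheezing")
        valid = [a for a in aucs if a is not None]
        assert valid and float(np.mean(valid)) >= 0.95

    def test_probabilities_in_unit_interval_and_empty_input(self):
        sentences, labels, note_ids = _marker_corpus(n=30, seed=7)
        cfg = NeuralConfig(**{**TINY.__dict__, "pretrain_epochs": 1, "finetune_epochs": 1})
        enc = mlm_pretrain(sentences, cfg)
        folds = make_folds(note_ids, seed=1)
        clf, _ = finetune_symptom(enc, sentences, labels, note_ids, folds)
        p = predict_proba(clf, sentences)
        assert ((p >= 0) & (p <= 1)).all()
        assert predict_proba(clf, []).size == 0

    def test_half_probability_is_labeled_yes(self):
        assert hard_labels([0.5, 0.49999, 0.50001]) == [YES, NO, YES]

    def test_overfit_memorizes_training_sentences(self):
        """After enough epochs on 50 sentences, thresholding at .5
        reproduces every training label."""
        sentences, labels, note_ids = _marker_corpus(n=50, seed=8)
        cfg = NeuralConfig(**{**TINY.__dict__, "pretrain_epochs": 4, "finetune_epochs": 30})
        enc = mlm_pretrain(sentences, cfg)
        folds = make_folds(note_ids, seed=4)
        clf, _ = finetune_symptom(enc, sentences, labels, note_ids, folds)
        assert hard_labels(predict_proba(clf, sentences)) == labels


class TestBowStub:
    def test_satisfies_predict_proba_contract(self):
        sentences, labels, _ = _marker_corpus(n=80, seed=9)
        clf = BowLogisticClassifier(seed=0).fit(sentences, labels)
        p = clf.predict_proba(sentences)
        assert p.shape == (80,)
        assert ((p >= 0) & (p <= 1)).all()
        # separable by construction: near-perfect recovery
        assert np.mean([h == l for h, l in zip(hard_labels(p), labels)]) > 0.97
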