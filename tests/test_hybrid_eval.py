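import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asthmanlp.corpus_io import NO, YES
from asthmanlp.hybrid_eval import (
    ConfusionCounts,
    ThresholdPair,
    agreement_kappa,
    confusion,
    consolidate,
    consolidate_all,
    corpus_summary,
    discrepancy_table,
    f1_from_percentages,
    f1_score,
    ppv_sensitivity_f1,
    roc_auc,
    tune_thresholds,
)

SYMS = ("cough", "dyspnea", "wheezing", "chest_tightness")


class TestConsolidate:
    def test_rule_yes_retained_above_cutoff(self):
        assert consolidate(YES, 0.6, ThresholdPair("cough", 0.2, 0.9)) == YES

    def test_rule_yes_flipped_below_cutoff(self):
        assert consolidate(YES, 0.1, ThresholdPair("cough", 0.2, 0.9)) == NO

    def test_rule_no_flipped_at_or_above_cutoff(self):
        assert consolidate(NO, 0.95, ThresholdPair("cough", 0.2, 0.9)) == YES
        assert consolidate(NO, 0.9, ThresholdPair("cough", 0.2, 0.9)) == YES
        assert consolidate(NO, 0.89, ThresholdPair("cough", 0.2, 0.9)) == NO

    def test_identity_configuration_never_flips(self):
        pair = ThresholdPair("cough", 0.0, math.inf)
        for label, p in product((YES, NO), (0.0, 0.5, 1.0)):
            assert consolidate(label, p, pair) == label

    def test_midpoint_thresholds_return_classifier_hard_labels(self):
        pair = ThresholdPair("cough", 0.5, 0.5)
        for label in (YES, NO):
            assert consolidate(label, 0.7, pair) == YES
            assert consolidate(label, 0.5, pair) == YES  # boundary: P >= .5
            assert consolidate(label, 0.3, pair) == NO

    def test_threshold_ranges_validated(self):
        with pytest.raises(ValueError):
            ThresholdPair("cough", 0.6, 0.9)
        with pytest.raises(ValueError):
            ThresholdPair("cough", 0.1, 0.4)


def _oracle_tune(rule, probs, gold, step):
    """Independent exhaustive search (same tie-break) for cross-checking."""
    n = round(0.5 / step)
    grid = [(0.0, math.inf)] + [
        (round(i * step, 10), round(1.0 - j * step, 10))
        for i in range(n + 1)
        for j in range(n + 1)
    ]
    best = None
    for ty, tn in grid:
        pred = [
            (NO if p < ty else YES) if r == YES else (YES if p >= tn else NO)
            for r, p in zip(rule, probs)
        ]
        tp = sum(g == YES and q == YES for g, q in zip(gold, pred))
        fp = sum(g == NO and q == YES for g, q in zip(gold, pred))
        fn = sum(g == YES and q == NO for g, q in zip(gold, pred))
        if tp + fp == 0 or tp + fn == 0:
            continue
        ppv, sens = tp / (tp + fp), tp / (tp + fn)
        if ppv + sens == 0:
            continue
        f1 = 2 * ppv * sens / (ppv + sens)
        key = (round(f1, 12), -ty, tn)  # equal-F1 ties resolved like the tuner
        if best is None or key > best[0]:
            best = (key, (ty, tn, f1))
    return best[1]


class TestTuneThresholds:
    def test_perfect_rules_return_identity(self):
        rule = gold = [YES, NO, YES, NO, YES]
        probs = [0.9, 0.4, 0.6, 0.2, 0.7]
        pair, f1 = tune_thresholds(rule, probs, gold, grid_step=0.05)
        assert (pair.t_yes, pair.t_no) == (0.0, math.inf)
        assert f1 == 1.0

    def test_flips_confident_false_positive(self):
        # one rule FP with p=0.05; true positives all have p > 0.3
        rule = [YES] * 6 + [NO] * 4
        gold = [YES] * 5 + [NO] * 5
        probs = [0.9, 0.8, 0.7, 0.6, 0.35, 0.05, 0.1, 0.2, 0.1, 0.3]
        pair, f1 = tune_thresholds(rule, probs, gold, grid_step=0.05)
        assert 0.05 < pair.t_yes <= 0.3
        assert f1 == 1.0
        assert f1 > f1_score(gold, rule)

    def test_matches_exhaustive_oracle_on_random_problems(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = 20
            gold = [YES if rng.random() < 0.5 else NO for _ in range(n)]
            rule = [
                g if rng.random() < 0.8 else (NO if g == YES else YES) for g in gold
            ]
            probs = [float(np.round(rng.random(), 3)) for _ in range(n)]
            try:
                pair, f1 = tune_thresholds(rule, probs, gold, grid_step=0.05)
            except ValueError:
                continue
            oty, otn, of1 = _oracle_tune(rule, probs, gold, 0.05)
            assert f1 == pytest.approx(of1, abs=1e-9)
            assert pair.t_yes == pytest.approx(oty)
            assert pair.t_no == otn or pair.t_no == pytest.approx(otn)

    def test_tuned_f1_never_below_rule_only(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = 30
            gold = [YES if rng.random() < 0.4 else NO for _ in range(n)]
            if len(set(gold)) < 2:
                continue
            rule = [
                g if rng.random() < 0.7 else (NO if g == YES else YES) for g in gold
            ]
            probs = [float(rng.random()) for _ in range(n)]
            base = f1_score(gold, rule)
            if base is None:
                continue
            _, tuned = tune_thresholds(rule, probs, gold, grid_step=0.1)
            assert tuned >= base - 1e-12


class TestConfusionAndRates:
    def test_enumerated_counts(self):
        c = confusion([YES, YES, NO, NO], [YES, NO, YES, NO])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_identical_sequences_no_errors(self):
        c = confusion([YES, NO, YES], [YES, NO, YES])
        assert c.fp == c.fn == 0

    def test_empty_sequences_all_zero(self):
        c = confusion([], [])
        assert c.total == 0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            confusion([YES], [YES, NO])

    def test_printed_hybrid_cough_sentence_metrics_reproduce(self):
        # PPV 97.17%, sensitivity 95.95% -> F1 0.966 at 3 decimals
        assert round(f1_from_percentages(97.17, 95.95), 3) == 0.966

    def test_perfect_rates(self):
        ppv, sens, f1 = ppv_sensitivity_f1(ConfusionCounts(tp=7, fp=0, tn=3, fn=0))
        assert (ppv, sens, f1) == (100.0, 100.0, 1.0)

    def test_direct_formula(self):
        ppv, sens, f1 = ppv_sensitivity_f1(ConfusionCounts(tp=1, fp=1, tn=0, fn=0))
        assert ppv == 50.0 and sens == 100.0
        assert round(f1, 3) == 0.667

    def test_undefined_denominators_reported_missing(self):
        ppv, sens, f1 = ppv_sensitivity_f1(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert ppv is None and sens is None and f1 is None


class TestAgreementKappa:
    def test_perfect_agreement(self):
        agreement, kappa = agreement_kappa([YES, NO, YES], [YES, NO, YES])
        assert agreement == 100.0 and kappa == 1.0

    def test_hand_evaluated_two_by_two_table(self):
        # a=40, b=10, c=10, d=40: p_o=0.8, p_e=0.5, kappa=0.6
        a = [YES] * 50 + [NO] * 50
        b = [YES] * 40 + [NO] * 10 + [YES] * 10 + [NO] * 40
        agreement, kappa = agreement_kappa(a, b)
        assert agreement == pytest.approx(80.0)
        assert kappa == pytest.approx(0.6)

    def test_chance_level_gives_zero_kappa(self):
        # constructed so p_o = p_e: one rater constant
        a = [YES] * 4
        b = [YES, YES, NO, NO]
        agreement, kappa = agreement_kappa(a, b)
        assert kappa == pytest.approx(0.0)

    def test_symmetry_under_rater_swap(self):
        rng = np.random.default_rng(8)
        a = [YES if rng.random() < 0.6 else NO for _ in range(50)]
        b = [YES if rng.random() < 0.4 else NO for _ in range(50)]
        assert agreement_kappa(a, b) == agreement_kappa(b, a)

    def test_matches_formula_on_random_tables(self):
        """Cross-check against direct formula evaluation and scikit-learn."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(21)
        for _ in range(300):
            counts = rng.integers(0, 12, size=4)  # a, b, c, d
            a = [YES] * (counts[0] + counts[1]) + [NO] * (counts[2] + counts[3])
            b = (
                [YES] * counts[0] + [NO] * counts[1]
                + [YES] * counts[2] + [NO] * counts[3]
            )
            n = len(a)
            if n == 0:
                continue
            p_o = (counts[0] + counts[3]) / n
            p_yes_a, p_yes_b = (counts[0] + counts[1]) / n, (counts[0] + counts[2]) / n
            p_e = p_yes_a * p_yes_b + (1 - p_yes_a) * (1 - p_yes_b)
            agreement, kappa = agreement_kappa(a, b)
            assert agreement == pytest.approx(100 * p_o)
            if abs(1 - p_e) < 1e-12:
                assert kappa is None
            else:
                assert kappa == pytest.approx((p_o - p_e) / (1 - p_e))
                assert kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-9)


def _auc_bruteforce(gold, probs):
    pos = [p for g, p in zip(gold, probs) if g == YES]
    neg = [p for g, p in zip(gold, probs) if g == NO]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([YES, YES, NO, NO], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_interleaved_case_pair_counted(self):
        assert roc_auc([YES, NO, YES, NO], [0.9, 0.8, 0.2, 0.1]) == 0.75

    def test_all_ties_give_half(self):
        assert roc_auc([YES, NO, YES, NO], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([YES, YES], [0.2, 0.4])

    def test_matches_pair_counting_oracle_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            gold = [YES if rng.random() < 0.5 else NO for _ in range(n)]
            if len(set(gold)) < 2:
                continue
            probs = [float(np.round(rng.random(), 1)) for _ in range(n)]
            got = roc_auc(gold, probs)
            assert got == pytest.approx(_auc_bruteforce(gold, probs))
            assert got == pytest.approx(
                roc_auc_score([g == YES for g in gold], probs)
            )


class TestDiscrepancyTable:
    def test_all_correct(self):
        gold = [YES, NO, YES]
        t = discrepancy_table(gold, gold, list(gold))
        assert t["both_right"] == 3
        assert t["rule_fp"] == t["neural_fn"] == 0

    def test_single_neural_flip(self):
        gold = [YES, NO]
        t = discrepancy_table(gold, gold, [NO, NO])
        assert t["neural_only_wrong"] == 1 and t["neural_fn"] == 1

    def test_strata_partition_all_units(self):
        rng = np.random.default_rng(2)
        n = 40
        gold = [YES if rng.random() < 0.5 else NO for _ in range(n)]
        rule = [YES if rng.random() < 0.5 else NO for _ in range(n)]
        neural = [YES if rng.random() < 0.5 else NO for _ in range(n)]
        t = discrepancy_table(gold, rule, neural)
        assert (
            t["both_right"] + t["rule_only_wrong"] + t["neural_only_wrong"] + t["both_wrong"]
            == n
        )


class TestCorpusSummary:
    def test_printed_corpus_percentages_reproduce(self):
        # cough: 1,363,713 of 127,763,086 sentences -> 1.07%
        assert round(100 * 1_363_713 / 127_763_086, 2) == 1.07
        # any symptom: 858,350 of 11,364,952 notes -> 7.55%
        assert round(100 * 858_350 / 11_364_952, 2) == 7.55

    def test_multi_symptom_units_counted_exclusively(self):
        sentence_labels = [
            {"cough": YES, "dyspnea": NO, "wheezing": YES, "chest_tightness": NO},
            {"cough": YES, "dyspnea": NO, "wheezing": NO, "chest_tightness": NO},
            {s: NO for s in SYMS},
        ]
        out = corpus_summary([], sentence_labels)["sentence"]
        assert out["n_symptoms"][1]["count"] == 1
        assert out["n_symptoms"][2]["count"] == 1
        assert out["any"]["count"] == 2
        assert out["symptoms"]["cough"]["percent"] == pytest.approx(66.67)

    def test_k_symptom_rows_sum_to_any(self):
        rng = np.random.default_rng(9)
        sentence_labels = [
            {s: (YES if rng.random() < 0.3 else NO) for s in SYMS} for _ in range(200)
        ]
        out = corpus_summary([], sentence_labels)["sentence"]
        assert sum(v["count"] for v in out["n_symptoms"].values()) == out["any"]["count"]


@settings(max_examples=60, derandomize=True)
@given(
    st.lists(
        st.tuples(st.sampled_from([YES, NO]), st.sampled_from([YES, NO])),
        min_size=1,
        max_size=30,
    )
)
def test_confusion_counts_partition(pairs):
    gold = [g for g, _ in pairs]
    pred = [p for _, p in pairs]
    assert confusion(gold, pred).total == len(pairs)
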