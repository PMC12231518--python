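"""Hybrid rule+classifier consolidation and the full evaluation suite.

The hybrid step modifies rule-based labels with classifier probabilities
through two per-symptom cutoffs: t_yes in [0, 0.5] applies to sentences the
rules called Yes (a probability *below* t_yes flips them to No), t_no in
[0.5, 1] applies to the rule-No group (a probability *at or above* t_no
flips them to Yes).  The boundary convention mirrors the classifier's own
"Yes when P >= .5" rule.  Cutoffs are tuned by exhaustive grid search
maximizing F1 against adjudicated labels, walking t_yes up from 0 and t_no
down from 1, with ties broken toward the do-nothing configuration.

Evaluation statistics cover everything a validation study of this kind
reports: confusion counts, PPV (precision), sensitivity (recall), F1,
percent agreement and Cohen's kappa between annotators, ROC AUC (the
pair-ranking probability, ties at 1/2), discrepancy strata between the two
algorithms, and corpus-frequency summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .corpus_io import NO, SYMPTOMS, YES


@dataclass(frozen=True)
class ThresholdPair:
    """Per-symptom hybrid cutoffs.

    ``t_no = math.inf`` is the documented sentinel for "never flip a
    rule-No" (the identity configuration sits just above 1); finite values
    must lie in [0.5, 1].
    """

    symptom: str
    t_yes: float
    t_no: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_yes <= 0.5:
            raise ValueError("t_yes must be in [0, 0.5]")
        if not (math.isinf(self.t_no) or 0.5 <= self.t_no <= 1.0):
            raise ValueError("t_no must be in [0.5, 1] or inf")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def consolidate(rule_label: str, probability: float, thresholds: ThresholdPair) -> str:
    """Apply the two-cutoff rule to one unit."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability outside [0, 1]")
    if rule_label == YES:
        return NO if probability < thresholds.t_yes else YES
    return YES if probability >= thresholds.t_no else NO


def consolidate_all(
    rule_labels: Sequence[str], probabilities: Sequence[float], thresholds: ThresholdPair
) -> list[str]:
    if len(rule_labels) != len(probabilities):
        raise ValueError("length mismatch")
    return [consolidate(r, p, thresholds) for r, p in zip(rule_labels, probabilities)]


def confusion(gold: Sequence[str], predicted: Sequence[str]) -> ConfusionCounts:
    """TP/FP/TN/FN over aligned Yes/No sequences."""
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted lengths differ")
    tp = fp = tn = fn = 0
    for g, p in zip(gold, predicted):
        if p == YES:
            if g == YES:
                tp += 1
            else:
                fp += 1
        else:
            if g == YES:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def ppv_sensitivity_f1(
    counts: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """(PPV %, sensitivity %, F1 on the 0-1 scale).

    PPV = TP/(TP+FP), sensitivity = TP/(TP+FN),
    F1 = 2*PPV*sens/(PPV+sens).  A statistic whose denominator is zero is
    returned as None (reported as missing).
    """
    ppv = 100.0 * counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    sens = 100.0 * counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    if ppv is None or sens is None or ppv + sens == 0:
        f1 = None
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens) / 100.0
    return ppv, sens, f1


def f1_from_percentages(ppv_pct: float, sensitivity_pct: float) -> float:
    """F1 (0-1) directly from PPV and sensitivity given as percentages."""
    if ppv_pct + sensitivity_pct == 0:
        raise ValueError("PPV + sensitivity is zero")
    return 2.0 * ppv_pct * sensitivity_pct / (ppv_pct + sensitivity_pct) / 100.0


def f1_score(gold: Sequence[str], predicted: Sequence[str]) -> float | None:
    return ppv_sensitivity_f1(confusion(gold, predicted))[2]


def tune_thresholds(
    rule_labels: Sequence[str],
    probabilities: Sequence[float],
    gold: Sequence[str],
    grid_step: float = 0.01,
    symptom: str = "",
) -> tuple[ThresholdPair, float]:
    """Exhaustive two-threshold grid search maximizing F1 against gold.

    The grid is t_yes in {0, step, ..., 0.5} x t_no in {1, 1-step, ...,
    0.5}, plus the identity configuration (t_yes=0, t_no=inf: never flip).
    Ties break toward the identity — smallest t_yes, then largest t_no.
    Grid points where F1 is undefined are skipped; if every point is
    skipped, a ValueError is raised.
    """
    if not (len(rule_labels) == len(probabilities) == len(gold)):
        raise ValueError("aligned sequences required")
    n_steps = round(0.5 / grid_step)
    if abs(n_steps * grid_step - 0.5) > 1e-9:
        raise ValueError("grid step must divide 0.5")
    yes_grid = [round(i * grid_step, 10) for i in range(n_steps + 1)]
    no_grid = [round(1.0 - i * grid_step, 10) for i in range(n_steps + 1)]

    candidates = [ThresholdPair(symptom, 0.0, math.inf)]
    candidates += [
        ThresholdPair(symptom, ty, tn) for ty in yes_grid for tn in no_grid
    ]

    best: tuple[ThresholdPair, float] | None = None
    for cand in candidates:
        f1 = f1_score(gold, consolidate_all(rule_labels, probabilities, cand))
        if f1 is None:
            continue
        if best is None or f1 > best[1] + 1e-12:
            best = (cand, f1)
        elif abs(f1 - best[1]) <= 1e-12:
            b = best[0]
            if (cand.t_yes, -cand.t_no) < (b.t_yes, -b.t_no):
                best = (cand, f1)
    if best is None:
        raise ValueError("F1 undefined at every grid point")
    return best


def agreement_kappa(
    labels_a: Sequence[str], labels_b: Sequence[str]
) -> tuple[float, float | None]:
    """(percent agreement, Cohen's kappa) between two aligned raters.

    kappa = (p_o - p_e)/(1 - p_e) with p_e from the product of marginals;
    when p_e = 1 (both raters constant and identical) kappa is undefined and
    returned as None.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("length mismatch")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty sequences")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    categories = sorted(set(labels_a) | set(labels_b))
    p_e = sum(
        (sum(a == c for a in labels_a) / n) * (sum(b == c for b in labels_b) / n)
        for c in categories
    )
    agreement = 100.0 * p_o
    if abs(1.0 - p_e) < 1e-12:
        return agreement, None
    return agreement, (p_o - p_e) / (1.0 - p_e)


def roc_auc(gold: Sequence[str], probabilities: Sequence[float]) -> float:
    """AUC as the pair-ranking probability (ties counted 1/2).

    Equals the probability a randomly chosen positive unit receives a higher
    probability than a randomly chosen negative one.  Raises on single-class
    gold.
    """
    if len(gold) != len(probabilities):
        raise ValueError("length mismatch")
    y = np.array([g == YES for g in gold], dtype=bool)
    p = np.asarray(probabilities, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(p)  # midranks implement the ties-at-1/2 convention
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def discrepancy_table(
    gold: Sequence[str], rule_labels: Sequence[str], neural_labels: Sequence[str]
) -> dict[str, int]:
    """Error strata of the two algorithms against gold.

    Keys: per-algorithm false positives/negatives and the four agreement
    strata (both_right, rule_only_wrong, neural_only_wrong, both_wrong);
    the strata partition all units.
    """
    if not (len(gold) == len(rule_labels) == len(neural_labels)):
        raise ValueError("length mismatch")
    out = {
        "rule_fp": 0,
        "rule_fn": 0,
        "neural_fp": 0,
        "neural_fn": 0,
        "both_right": 0,
        "rule_only_wrong": 0,
        "neural_only_wrong": 0,
        "both_wrong": 0,
    }
    for g, r, m in zip(gold, rule_labels, neural_labels):
        if r != g:
            out["rule_fp" if r == YES else "rule_fn"] += 1
        if m != g:
            out["neural_fp" if m == YES else "neural_fn"] += 1
        if r == g and m == g:
            out["both_right"] += 1
        elif r != g and m == g:
            out["rule_only_wrong"] += 1
        elif r == g and m != g:
            out["neural_only_wrong"] += 1
        else:
            out["both_wrong"] += 1
    return out


def corpus_summary(
    note_labels: Sequence[Mapping[str, str]],
    sentence_labels: Sequence[Mapping[str, str]],
) -> dict:
    """Per-symptom positive counts/percentages at both levels, plus the
    distribution of how many symptoms co-occur per unit.

    Percentages are count/total*100, reported to 2 decimals.  A unit with k
    positive symptoms counts once in the "k symptoms" row; the k-symptom
    rows sum to the any-symptom count.
    """

    def level(units: Sequence[Mapping[str, str]]) -> dict:
        total = len(units)
        pct = lambda c: round(100.0 * c / total, 2) if total else 0.0
        per_symptom = {}
        for sym in SYMPTOMS:
            c = sum(u[sym] == YES for u in units)
            per_symptom[sym] = {"count": c, "percent": pct(c)}
        k_counts = {k: 0 for k in range(1, len(SYMPTOMS) + 1)}
        any_count = 0
        for u in units:
            k = sum(u[s] == YES for s in SYMPTOMS)
            if k:
                any_count += 1
                k_counts[k] += 1
        return {
            "total": total,
            "symptoms": per_symptom,
            "any": {"count": any_count, "percent": pct(any_count)},
            "n_symptoms": {
                k: {"count": c, "percent": pct(c)} for k, c in k_counts.items()
            },
        }

    return {"sentence": level(sentence_labels), "note": level(note_labels)}
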