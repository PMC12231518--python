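"""Consolidate rule labels with classifier probabilities and evaluate.

The hybrid step uses two per-symptom cutoffs tuned by F1 against gold:
t_yes flips overconfident rule-Yes calls to No when the classifier
probability falls below it, t_no flips rule-No calls to Yes above it.  The
do-nothing configuration is always in the search grid, so the tuned hybrid
can never score below the rules alone on the tuning data.
"""

from asthmanlp import (
    NO,
    YES,
    confusion,
    consolidate_all,
    f1_from_percentages,
    ppv_sensitivity_f1,
    roc_auc,
    tune_thresholds,
)

# a small worked set: rule labels, classifier probabilities, gold
gold = [YES, YES, YES, YES, NO, NO, NO, NO, NO, NO]
rule = [YES, YES, YES, NO, YES, NO, NO, NO, NO, NO]   # one FN, one FP
probs = [0.95, 0.88, 0.74, 0.81, 0.04, 0.10, 0.22, 0.08, 0.15, 0.30]

base_counts = confusion(gold, rule)
ppv, sens, f1 = ppv_sensitivity_f1(base_counts)
print(f"rule-only:  PPV {ppv:.1f}%  sensitivity {sens:.1f}%  F1 {f1:.3f}")

pair, tuned_f1 = tune_thresholds(rule, probs, gold, grid_step=0.05)
hybrid = consolidate_all(rule, probs, pair)
print(f"tuned cutoffs: t_yes={pair.t_yes:.2f} (rule-Yes group), "
      f"t_no={pair.t_no:.2f} (rule-No group)")
print(f"hybrid:     F1 {tuned_f1:.3f}  labels {hybrid}")

print(f"classifier ranking quality, AUC: {roc_auc(gold, probs):.3f}")

# the same F1 formula applied to published-style percentage inputs
print("F1 from PPV 97.17% and sensitivity 95.95%:",
      round(f1_from_percentages(97.17, 95.95), 3))
print("The hybrid fixes both rule errors here because the classifier is")
print("confident and right exactly where the rules are wrong.")
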