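# Methods

This note records what the package computes, the assumptions behind each
component, the defaults that matter, and the limits of what the test suite
can show.  Everything quantitative stated here is computed by the tests or
by `scripts/acceptance.py`; nothing is quoted from external runs.

## Task and granularity

Four symptoms — cough, dyspnea, wheezing, chest tightness — are decided
independently as Yes/No at the sentence level; a note is Yes for a symptom
iff at least one of its sentences is.  "Yes" means *current patient
finding*: a negated, historical, family-member, templated-warning,
questionnaire/instruction-section or anxiety-attributed mention is No, each
with its own reason code, so every negative is auditable.

## Preprocessing

Fixed order: lowercase + character whitelist → sentence split → section
detection → tokenization → term standardization.

* **Normalization** keeps lowercase letters, digits, space, period, comma,
  question mark and semicolon; everything else becomes a space and runs
  collapse.  The map is idempotent.
* **Sentence splitting** breaks at `.`/`?` followed by space or end; a small
  guard list ("dr.", "mg.", …) blocks false splits.  Semicolons and commas
  stay inside the sentence as clause punctuation — necessary because
  negation scope must distribute *across* commas but stop at semicolons.
* **Tokenization** splits on whitespace with trailing punctuation as its own
  token; a sentence's `text` is defined as the space-joined token stream so
  the tokens↔text invariant is exact.
* **Section detection** matches configurable header phrases that fill an
  entire clause ("review of systems", "instructions", …); each sentence
  carries the most recent header's label, `body` before any header.  Header
  sentences remain sentences, labeled with their own section.  Headers that
  merge into a following clause after colon removal ("instructions return
  if…") are deliberately *not* treated as headers: a header must be a
  standalone clause.
* **Standardization** expands whole-token abbreviations (longest key first,
  left to right, single pass, acyclic map), then corrects out-of-vocabulary
  tokens that sit at edit distance 1 of exactly one *symptom-relevant*
  word.  The known-word list ships with a few hundred common
  English/clinical words precisely so that "tough", "couch", "might",
  "son" etc. are never rewritten into symptom terms; correction targets are
  restricted to the symptom vocabulary, never general English.

## Lexicons

One editable text file per symptom list and per cue category; curation is
first-class because these lists are, in practice, refined by iterative
chart review.  Cue categories: negated, uncertain, definite, history,
nonpatient, general_description, exclusion_context (anxiety).  Chest
tightness additionally fires through a proximity rule: a token from
{tight, tightness, tighter} and "chest" within at most 3 intervening words,
either order.  Whether such distance rules should apply to the other three
symptoms is an open modeling question; only chest tightness carries one by
default because its surface realizations genuinely separate the two anchor
words ("chest feels quite tight").

`train_embedding` is a seeded skip-gram negative-sampling model (numpy;
linearly decaying step size, gradient clipping, unigram^0.75 noise) and
`nearest_terms` the cosine-ranked lookup used to surface misspelling and
synonym candidates for curation.  The embedding supports the curation
workflow; it is not part of the decision path.

## Rule engine

Cues divide into two families:

* **Polarity cues** (negated, definite, uncertain) scope *forward* from the
  cue, distributing across comma/"or"/"and" list items; scope ends at a
  semicolon, a contrast word ("but", "however"), a later polarity cue of a
  different category, or a list item opening with an affirming qualifier
  ("mild", "worsening", …) — the reading under which "no wheezing, mild
  sob" negates only wheezing while "denied fever, chills, wheezes, gerd, or
  any new medication" negates the whole list.
* **Attribution cues** (history, nonpatient, general_description,
  exclusion_context) scope over their whole semicolon-delimited clause in
  both directions, because temporal and attributional modifiers are not
  word-order-bound ("cough started a couple of months before").

Priority when several cues govern one mention: nonpatient >
general_description > history > polarity; within the polarity family the
cue nearest the mention wins, which is how "positive for" overrides an
earlier negation.  Design choices that were genuinely open and are fixed
here as configuration defaults: uncertain mentions count as present
(UNCERTAIN_AFFIRMED → Yes; switchable, in which case the non-standard
reason UNCERTAIN_EXCLUDED appears); anxiety-context exclusion is
note-scoped (any anxiety term anywhere in the note suppresses all symptom
labels; switchable to sentence scope); post-position negation ("… is
denied") is off by default since pre-position cues dominate clinical
prose.  Section exclusion defaults to {instructions, questionnaire,
problem_list}.

## Transformer classifier

A compact BERT-style encoder written directly in numpy: learned word +
position embeddings, pre-norm multi-head self-attention blocks with GELU
feed-forward layers, final layer norm.  All gradients are hand-derived and
verified against central finite differences in the test suite; Adam is the
optimizer; every random draw flows from one seed, so training is exactly
reproducible and model state round-trips through serialization bitwise.

Pretraining is masked language modeling: per sentence, exactly
round(0.20·n) real tokens are selected; of those 80 % become `[MASK]`,
10 % a random word, 10 % stay (the standard recipe; the split ratios are
config fields).  Fine-tuning attaches a per-symptom sigmoid head to the
`[CLS]` position and trains through the encoder with 5-fold
cross-training-validation; folds are assigned **by note**, so sentences of
one note never straddle the train/validation boundary (the leakage-safe
choice where the unit was ambiguous).  A held-out fold containing a single
class reports its AUC as missing and the run continues.  Hard labels use
the P ≥ 0.5 ⇒ Yes convention, including the boundary.

Two named configurations: the **desk default** (hidden 64, 2 layers, 2
heads, 128-token sequences, batch 16, lr 1e-4) trains on synthetic corpora
in seconds-to-minutes on one CPU; `FULL_SCALE_CONFIG` carries the full-scale
settings (512-token sequences, lr 1e-5, batch 32, 12×768 encoder) for
GPU-scale corpora.  Tests and the acceptance script use a *tiny* variant
(hidden 32, 1 layer, lr 1e-3, ~200 sentences) chosen as the smallest
problem on which the sanity properties — monotone MLM loss, cross-validated
AUC ≥ 0.95 on a marker-token labeling, perfect memorization of 50
sentences — are stable across seeds.

The downstream contract is only `predict_proba(sentences) -> p ∈ [0,1]`;
`BowLogisticClassifier` (binary bag-of-words + logistic regression) is a
substitutable stub, and is the pipeline's default classifier so that
end-to-end runs stay fast; `classifier: transformer` switches to the
encoder.

## Hybrid consolidation

Per symptom, cutoffs (t_yes ∈ [0, 0.5], t_no ∈ [0.5, 1]): rule-Yes flips
to No when p < t_yes (strict), rule-No flips to Yes when p ≥ t_no — the
boundary convention mirrors the classifier's own P ≥ 0.5 rule.  Tuning is
an exhaustive grid search (default step 0.01) walking t_yes up from 0 and
t_no down from 1, maximizing F1 of the consolidated labels against
adjudicated labels; the identity configuration (t_yes = 0, t_no just above
1, encoded as `math.inf`) is always a candidate and ties break toward it,
so tuned F1 ≥ rule-only F1 on the tuning data is a theorem the tests
confirm empirically.  Grid points with undefined F1 are skipped; if all
are, tuning errors out.  Thresholds are tuned and applied at the sentence
level; note labels derive from consolidated sentence labels by OR.  When
tuning and evaluation use the same split the tuned F1 is optimistically
biased; the pipeline supports tuning on a separate simulated split, and
users evaluating on real annotations should hold one out.

## Evaluation statistics

PPV = TP/(TP+FP) and sensitivity = TP/(TP+FN) are reported as percentages
to 2 decimals, F1 on the 0–1 scale to 3 decimals.  Undefined denominators
report as missing rather than 0.  Percent agreement is identical/total×100;
Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from marginal products, missing
when p_e = 1.  AUC is the probability a random positive outranks a random
negative with ties at ½, computed via midranks — identical to exhaustive
pair counting, which the tests verify on a thousand small instances.
Discrepancy tables stratify units into both-right / rule-only-wrong /
neural-only-wrong / both-wrong per symptom; corpus summaries report
per-symptom and any-symptom frequencies plus the exclusive k-symptom
co-occurrence rows, which sum to the any-symptom count.

## Synthetic corpus

The generator emulates the documentation-pattern taxonomy, not clinical
realism: sectioned notes whose sentence counts follow a negative binomial
with mean 11.2 and dispersion 0.4 (the scale and overdispersion of
deployment-time notes, which are far shorter than annotation-enriched
ones); per-note symptom mention probabilities default to 0.30/0.25/0.20/
0.15 (cough/dyspnea/wheezing/chest tightness) — deliberately enriched, like
a keyword-selected annotation corpus, rather than matching the ~1 %
prevalence of a raw implementation stream, since the corpus's job is to
train and test classifiers.  Context classes and default conditional
probabilities: affirmed .45, negated .20, list-negated .10, history .07,
uncertain .05, nonpatient .05, general-description .05, anxiety-context
.03; two adversarial classes (5-item denial lists, post-position negation)
default to 0 and exist for the difficulty split.  Abbreviated (15 %) and
misspelled (10 %) surface forms come from curated tables whose entries the
standardizer provably repairs, so surface noise never changes gold.
Anxiety-context generation is note-scoped to match the rule default.

Because covered-pattern corpora are generated *from* templates the rule
patterns fully cover, the rule engine's 100 % gold recovery on them is a
consistency check of engine + generator + preprocessing round-trip — it
demonstrates internal correctness, not real-world accuracy.  Real notes
contain constructions outside the taxonomy; the adversarial classes probe
two known ones, and the discrepancy machinery exists to surface the rest.

## Numerical and degenerate-input conventions

Seeded `numpy` generators everywhere; single-threaded; two runs with one
seed are byte-identical through the full pipeline.  Empty note → empty
sentence list → note-level No for all symptoms.  Empty prediction input →
empty output.  Sequences longer than the configured maximum are truncated,
not rejected.  Threshold grids use exact decimal rounding to avoid
floating-point drift in grid membership; F1 comparisons in the tuner use a
1e-12 tolerance with deterministic tie-breaks.

## Known limitations

* Scoping is clause/list-based; no syntactic parsing, so long-range or
  post-position negation ("symptoms have not recurred") is missed unless
  the post-position option is enabled with its own cue list.
* The shipped lexicons are reconstructions around the documented seed
  phrases, not a clinically curated inventory; real deployments must edit
  them (they are plain text files for exactly that reason).
* The desk-scale transformer demonstrates the training contract, not
  full-scale accuracy; no pretrained weights are downloaded or shipped.
* Gold labels in the generator encode one fixed reading of uncertainty and
  anxiety attribution; annotator disagreement in real corpora is modeled
  only through the agreement/κ tooling, not simulated.
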