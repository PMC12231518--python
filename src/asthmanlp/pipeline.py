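"""End-to-end pipeline: simulate/ingest -> preprocess -> rules -> neural ->
hybrid -> evaluate, with a reproducibility manifest.

A run is driven by one structured (YAML) config and one top-level seed;
every stage's randomness is derived from that seed, so identical config +
seed gives identical outputs.  Each run writes exactly one
``manifest.json`` recording the command, the full config echo, the seed,
and digests of every input and output file.  On failure, partial outputs
are removed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .corpus_io import (
    NO,
    SYMPTOMS,
    YES,
    ClinicalNote,
    read_notes,
    write_gold,
    write_notes,
    write_predictions,
)
from .hybrid_eval import (
    ThresholdPair,
    confusion,
    consolidate_all,
    corpus_summary,
    ppv_sensitivity_f1,
    tune_thresholds,
)
from .lexicon import load_lexicons
from .preprocess import default_config, preprocess_note
from .rule_engine import (
    RuleConfig,
    classify_note,
    note_prediction_records,
    sentence_prediction_records,
)
from .synthgen import SynthConfig, generate_corpus

DEFAULT_STAGES = ("simulate", "rules", "neural", "hybrid", "evaluate")


class StageError(RuntimeError):
    """A pipeline stage failed or is missing its input."""


@dataclass
class RunManifest:
    command: str
    config: Mapping[str, Any]
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True), encoding="utf-8")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _rule_config(section: Mapping[str, Any]) -> RuleConfig:
    kwargs: dict[str, Any] = {}
    if "excluded_sections" in section:
        kwargs["excluded_sections"] = frozenset(section["excluded_sections"])
    for key in ("uncertain_is_present", "context_scope", "post_position_negation"):
        if key in section:
            kwargs[key] = section[key]
    return RuleConfig(**kwargs)


def run_pipeline(
    config: Mapping[str, Any] | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Execute the configured stages and write predictions, metrics and a
    manifest into ``out_dir``.

    ``config`` is a mapping or a path to a YAML file.  ``seed`` overrides
    the config's seed.  Raises :class:`StageError` naming the stage on a
    missing input; partially written outputs are removed before the error
    propagates.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text(encoding="utf-8")) or {}
    config = dict(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        command="pipeline",
        config=config,
        seed=seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    created: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        created.append(path)
        manifest.outputs[name] = file_digest(path)
        return path

    try:
        _run_stages(config, stages, seed, out, manifest, emit)
    except Exception:
        for path in created:
            path.unlink(missing_ok=True)
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return manifest


def _run_stages(config, stages, seed, out, manifest, emit) -> None:
    lex = load_lexicons(config.get("lexicons"))
    prep_cfg = default_config()
    rule_cfg = _rule_config(config.get("rules", {}))

    # ---- corpus: simulate or ingest -------------------------------------
    gold_sentence: dict[tuple[str, int], Mapping[str, str]] | None = None
    gold_note: dict[str, Mapping[str, str]] | None = None
    if "simulate" in stages:
        sim_kwargs = dict(config.get("simulate", {}))
        sim_kwargs["seed"] = seed
        synth = generate_corpus(SynthConfig(**sim_kwargs), lex)
        notes = [sn.note for sn in synth]
        gold_sentence = {
            (g.note_id, g.sentence_index): g.labels for sn in synth for g in sn.gold
        }
        gold_note = {sn.note.note_id: sn.note_gold.labels for sn in synth}
        emit("notes.csv", lambda p: write_notes(notes, p))
        emit(
            "gold_sentence.csv",
            lambda p: write_gold([g for sn in synth for g in sn.gold], p),
        )
    else:
        notes_file = config.get("notes_file")
        if not notes_file or not Path(notes_file).exists():
            raise StageError("ingest: notes_file missing or not found")
        manifest.inputs["notes_file"] = file_digest(notes_file)
        notes = read_notes(notes_file)

    # ---- preprocess + rules ---------------------------------------------
    per_note_sentences = {n.note_id: preprocess_note(n, prep_cfg) for n in notes}
    if "rules" not in stages:
        raise StageError("rules: downstream stages require the rules stage")
    sentence_labels = {}
    note_labels = {}
    for n in notes:
        sls, nl = classify_note(per_note_sentences[n.note_id], lex, rule_cfg)
        sentence_labels[n.note_id] = sls
        note_labels[n.note_id] = nl
    all_sls = [sl for n in notes for sl in sentence_labels[n.note_id]]
    emit(
        "sentence_rule_predictions.jsonl",
        lambda p: write_predictions(sentence_prediction_records(all_sls), p),
    )
    emit(
        "note_rule_predictions.csv",
        lambda p: write_predictions(
            note_prediction_records([note_labels[n.note_id] for n in notes]), p
        ),
    )

    # ---- neural probabilities -------------------------------------------
    probs: dict[str, list[float]] | None = None
    flat = [(n.note_id, s) for n in notes for s in per_note_sentences[n.note_id]]
    if "neural" in stages:
        if gold_sentence is None:
            raise StageError("neural: training labels unavailable (no simulate stage)")
        probs = _neural_probabilities(config, seed, flat, gold_sentence)
        emit("probabilities.csv", lambda p: _write_probs(flat, probs, p))

    # ---- hybrid ----------------------------------------------------------
    final_sentence = {
        sym: [sentence_labels[nid][s.sentence_index].labels[sym] for nid, s in flat]
        for sym in SYMPTOMS
    }
    thresholds: dict[str, ThresholdPair] = {}
    if "hybrid" in stages and probs is not None:
        if gold_sentence is None:
            raise StageError("hybrid: tuning requires gold labels")
        step = float(config.get("hybrid", {}).get("grid_step", 0.01))
        for sym in SYMPTOMS:
            gold = [gold_sentence[(nid, s.sentence_index)][sym] for nid, s in flat]
            pair, _ = tune_thresholds(
                final_sentence[sym], probs[sym], gold, grid_step=step, symptom=sym
            )
            thresholds[sym] = pair
            final_sentence[sym] = consolidate_all(final_sentence[sym], probs[sym], pair)
        # t_no = null encodes the "never flip" sentinel (math.inf)
        emit("thresholds.json", lambda p: p.write_text(
            json.dumps(
                {
                    s: {
                        "t_yes": t.t_yes,
                        "t_no": None if not np.isfinite(t.t_no) else t.t_no,
                    }
                    for s, t in thresholds.items()
                },
                indent=2,
            ),
            encoding="utf-8",
        ))

    # note-level final labels: OR of final sentence labels
    final_note: dict[str, dict[str, str]] = {n.note_id: {} for n in notes}
    for sym in SYMPTOMS:
        for (nid, _s), lab in zip(flat, final_sentence[sym]):
            if lab == YES:
                final_note[nid][sym] = YES
        for n in notes:
            final_note[n.note_id].setdefault(sym, NO)

    # ---- evaluate ---------------------------------------------------------
    if "evaluate" in stages:
        if gold_sentence is None:
            raise StageError("evaluate: gold labels unavailable")
        rows = []
        for sym in SYMPTOMS:
            gold_s = [gold_sentence[(nid, s.sentence_index)][sym] for nid, s in flat]
            pred_s = final_sentence[sym]
            gold_n = [gold_note[n.note_id][sym] for n in notes]
            pred_n = [final_note[n.note_id][sym] for n in notes]
            for level, g, p in (("sentence", gold_s, pred_s), ("note", gold_n, pred_n)):
                counts = confusion(g, p)
                ppv, sens, f1 = ppv_sensitivity_f1(counts)
                rows.append(
                    {
                        "symptom": sym,
                        "level": level,
                        "tp": counts.tp,
                        "fp": counts.fp,
                        "tn": counts.tn,
                        "fn": counts.fn,
                        "ppv_pct": None if ppv is None else round(ppv, 2),
                        "sensitivity_pct": None if sens is None else round(sens, 2),
                        "f1": None if f1 is None else round(f1, 3),
                    }
                )
        emit("metrics.csv", lambda p: _write_rows(rows, p))
        summary = corpus_summary(
            [final_note[n.note_id] for n in notes],
            [
                {sym: final_sentence[sym][i] for sym in SYMPTOMS}
                for i in range(len(flat))
            ],
        )
        emit("summary.json", lambda p: p.write_text(
            json.dumps(summary, indent=2), encoding="utf-8"
        ))


def _neural_probabilities(config, seed, flat, gold_sentence):
    """Train the configured classifier per symptom and predict sentence
    probabilities for the whole corpus."""
    section = dict(config.get("neural", {}))
    kind = section.pop("classifier", "bow")
    sentences = [list(s.tokens) for _nid, s in flat]
    note_ids = [nid for nid, _s in flat]
    probs: dict[str, list[float]] = {}
    if kind == "bow":
        from .neural_clf import BowLogisticClassifier

        for sym in SYMPTOMS:
            labels = [gold_sentence[(nid, s.sentence_index)][sym] for nid, s in flat]
            if len(set(labels)) < 2:
                probs[sym] = [0.0] * len(flat)
                continue
            clf = BowLogisticClassifier(seed=seed).fit(sentences, labels)
            probs[sym] = [float(p) for p in clf.predict_proba(sentences)]
    elif kind == "transformer":
        from .neural_clf import (
            NeuralConfig,
            finetune_symptom,
            make_folds,
            mlm_pretrain,
            predict_proba,
        )

        ncfg = NeuralConfig(**{**section, "seed": seed})
        encoder = mlm_pretrain(sentences, ncfg)
        folds = make_folds(note_ids, seed=seed)
        for sym in SYMPTOMS:
            labels = [gold_sentence[(nid, s.sentence_index)][sym] for nid, s in flat]
            if len(set(labels)) < 2:
                probs[sym] = [0.0] * len(flat)
                continue
            clf, _ = finetune_symptom(encoder, sentences, labels, note_ids, folds, sym)
            probs[sym] = [float(p) for p in predict_proba(clf, sentences)]
    else:
        raise StageError(f"neural: unknown classifier kind {kind!r}")
    return probs


def _write_probs(flat, probs, path: Path) -> None:
    import csv

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "sentence_index"] + list(SYMPTOMS))
        for i, (nid, s) in enumerate(flat):
            writer.writerow(
                [nid, s.sentence_index] + [f"{probs[sym][i]:.6f}" for sym in SYMPTOMS]
            )


def _write_rows(rows: Sequence[Mapping[str, Any]], path: Path) -> None:
    import csv

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
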