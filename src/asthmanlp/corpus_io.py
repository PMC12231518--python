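"""Data model and I/O for clinical notes, gold labels, and predictions.

Notes, gold labels, note-level predictions and metrics travel as UTF-8 CSV
with a header row (comma delimiter, standard quote-escaping); sentence-level
predictions travel as JSON Lines, one record per line.  Reading back what a
writer produced is always the identity.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

SYMPTOMS = ("cough", "dyspnea", "wheezing", "chest_tightness")

YES = "Yes"
NO = "No"


class CorpusFormatError(ValueError):
    """Raised when a record file violates the documented dialect."""


@dataclass(frozen=True)
class ClinicalNote:
    """One free-text clinical note with its routing metadata.

    All metadata fields are always present; ``"unknown"`` is the
    conventional placeholder when the source system did not supply one.
    """

    note_id: str
    patient_id: str
    text: str
    encounter_type: str = "unknown"
    note_type: str = "unknown"
    department: str = "unknown"


@dataclass(frozen=True)
class NoteFilterConfig:
    """Metadata allowlists for note selection.

    An empty set for any field means "allow all" for that field.  This is
    deliberate: the shipped default filters nothing, and restriction is an
    explicit user decision.
    """

    allowed_encounter_types: frozenset[str] = frozenset()
    allowed_note_types: frozenset[str] = frozenset()
    allowed_departments: frozenset[str] = frozenset()

    def admits(self, note: ClinicalNote) -> bool:
        for allowed, value in (
            (self.allowed_encounter_types, note.encounter_type),
            (self.allowed_note_types, note.note_type),
            (self.allowed_departments, note.department),
        ):
            if allowed and value not in allowed:
                return False
        return True


@dataclass(frozen=True)
class GoldRecord:
    """Adjudicated per-sentence gold labels for the four symptoms."""

    note_id: str
    sentence_index: int
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sentence_index < 0:
            raise ValueError("sentence_index must be >= 0")
        for sym in SYMPTOMS:
            if self.labels.get(sym) not in (YES, NO):
                raise ValueError(f"missing or invalid gold label for {sym!r}")


@dataclass(frozen=True)
class SentencePrediction:
    """One sentence-level decision for one symptom, with its audit trail."""

    note_id: str
    sentence_index: int
    symptom: str
    label: str
    reason: str = ""
    evidence: str = ""


@dataclass(frozen=True)
class NotePrediction:
    """Note-level Yes/No decisions for all four symptoms."""

    note_id: str
    labels: dict[str, str] = field(default_factory=dict)


_NOTE_FIELDS = ["note_id", "patient_id", "text", "encounter_type", "note_type", "department"]


def read_notes(path: str | Path, format: str = "delimited") -> list[ClinicalNote]:
    """Read clinical notes from ``path``.

    ``format`` is ``"delimited"`` (CSV with header) or
    ``"line-delimited-records"`` (JSONL, one object per line).  Text is
    preserved byte-for-byte.  A malformed record or a duplicate note_id is an
    error naming the offending line.
    """
    path = Path(path)
    notes: list[ClinicalNote] = []
    seen: set[str] = set()
    if format == "delimited":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            if "note_id" not in reader.fieldnames or "text" not in reader.fieldnames:
                raise CorpusFormatError(f"{path}: header must include note_id and text")
            for lineno, row in enumerate(reader, start=2):
                notes.append(_note_from_mapping(row, path, lineno, seen))
    elif format == "line-delimited-records":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{lineno}: invalid JSON record") from exc
                notes.append(_note_from_mapping(row, path, lineno, seen))
    else:
        raise ValueError(f"unknown format {format!r}")
    return notes


def _note_from_mapping(row, path, lineno, seen: set[str]) -> ClinicalNote:
    note_id = row.get("note_id")
    if note_id is None or note_id == "":
        raise CorpusFormatError(f"{path}:{lineno}: record missing note_id")
    if row.get("text") is None:
        raise CorpusFormatError(f"{path}:{lineno}: record missing text field")
    if note_id in seen:
        raise CorpusFormatError(f"{path}:{lineno}: duplicate note_id {note_id!r}")
    seen.add(note_id)
    return ClinicalNote(
        note_id=note_id,
        patient_id=row.get("patient_id", "unknown") or "unknown",
        text=row["text"],
        encounter_type=row.get("encounter_type", "unknown") or "unknown",
        note_type=row.get("note_type", "unknown") or "unknown",
        department=row.get("department", "unknown") or "unknown",
    )


def write_notes(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    """Write notes as CSV with header; round-trips through read_notes."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_NOTE_FIELDS)
        writer.writeheader()
        for note in notes:
            writer.writerow({f: getattr(note, f) for f in _NOTE_FIELDS})


def filter_notes(
    notes: Sequence[ClinicalNote], cfg: NoteFilterConfig
) -> list[ClinicalNote]:
    """Keep exactly the notes whose metadata pass every allowlist, in order.

    Idempotent: filtering a filtered sequence with the same config is a
    no-op.
    """
    return [n for n in notes if cfg.admits(n)]


_GOLD_FIELDS = ["note_id", "sentence_index"] + list(SYMPTOMS)


def write_gold(records: Iterable[GoldRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_GOLD_FIELDS)
        for rec in records:
            writer.writerow(
                [rec.note_id, rec.sentence_index] + [rec.labels[s] for s in SYMPTOMS]
            )


def read_gold(path: str | Path) -> list[GoldRecord]:
    path = Path(path)
    out: list[GoldRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    GoldRecord(
                        note_id=row["note_id"],
                        sentence_index=int(row["sentence_index"]),
                        labels={s: row[s] for s in SYMPTOMS},
                    )
                )
            except (KeyError, ValueError) as exc:
                raise CorpusFormatError(f"{path}:{lineno}: malformed gold record") from exc
    return out


def write_predictions(records: Sequence, path: str | Path) -> None:
    """Write a homogeneous prediction sequence to ``path``.

    Sentence-level predictions go out as JSONL, note-level as CSV; mixing
    granularities in one call is a contract violation.
    """
    records = list(records)
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError("mixed prediction granularities in one file")
    path = Path(path)
    if records and isinstance(records[0], NotePrediction):
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["note_id"] + list(SYMPTOMS))
            for rec in records:
                writer.writerow([rec.note_id] + [rec.labels[s] for s in SYMPTOMS])
    else:
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(
                    json.dumps(
                        {
                            "note_id": rec.note_id,
                            "sentence_index": rec.sentence_index,
                            "symptom": rec.symptom,
                            "label": rec.label,
                            "reason": rec.reason,
                            "evidence": rec.evidence,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )


def read_sentence_predictions(path: str | Path) -> list[SentencePrediction]:
    out: list[SentencePrediction] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                row = json.loads(line)
                out.append(SentencePrediction(**row))
            except (json.JSONDecodeError, TypeError) as exc:
                raise CorpusFormatError(f"{path}:{lineno}: malformed prediction") from exc
    return out


def read_note_predictions(path: str | Path) -> list[NotePrediction]:
    out: list[NotePrediction] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(
                NotePrediction(note_id=row["note_id"], labels={s: row[s] for s in SYMPTOMS})
            )
    return out
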