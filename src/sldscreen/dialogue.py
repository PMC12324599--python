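"""Data model and readers/writers for diarized, scenario-segmented transcripts.

A corpus is a flat sequence of utterances, each attributed to a speaker role
(examiner or patient) inside one (subject, scenario) dialogue. Two on-disk
dialects are supported:

* ``jsonl`` — one JSON object per utterance with keys ``subject_id``,
  ``scenario_id``, ``index``, ``speaker``, ``text``;
* ``tsv`` — the same five columns with a header row; tab characters inside
  text are escaped as ``\\t``.

Ground-truth annotations (present only for synthetic or fixture data) live in
a sidecar JSON-lines file next to the transcript (``<stem>.truth.jsonl``) so
transcripts stay plain and diff-friendly. The round trip
``read_corpus(write_corpus(x))`` is lossless, annotations included.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import CorpusParseError, DuplicateUtteranceError
from .knowledge import canonical_scenario, included_scenarios
from .profiles import FeatureProfile

__all__ = [
    "Utterance",
    "TruthAnnotation",
    "DiarizedDialogue",
    "SubjectRecord",
    "read_corpus",
    "write_corpus",
    "filter_included",
    "truth_sidecar_path",
]

Dialect = Literal["jsonl", "tsv"]

_SPEAKER_ALIASES = {
    "e": "examiner",
    "examiner": "examiner",
    "p": "patient",
    "patient": "patient",
}

_WS = re.compile(r"\s+")


def normalize_whitespace(text: str) -> str:
    """Collapse whitespace runs (spaces, tabs, newlines) and strip the ends."""
    return _WS.sub(" ", text).strip()


class Utterance(BaseModel):
    """One turn of speech attributed to a role."""

    model_config = ConfigDict(frozen=True)

    index: int
    speaker: Literal["examiner", "patient"]
    text: str

    @field_validator("index")
    @classmethod
    def _nonnegative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("utterance index must be non-negative")
        return v

    @field_validator("text")
    @classmethod
    def _normalize(cls, v: str) -> str:
        v = normalize_whitespace(v)
        if not v:
            raise ValueError("utterance text is empty after whitespace normalization")
        return v


class TruthAnnotation(BaseModel):
    """Planted ground truth for one synthetic dialogue."""

    model_config = ConfigDict(frozen=True)

    profile: FeatureProfile
    label: int
    planted: dict[str, tuple[int, ...]] = {}

    @field_validator("label")
    @classmethod
    def _binary(cls, v: int) -> int:
        if v not in (0, 1):
            raise ValueError("truth label must be 0 or 1")
        return v


class DiarizedDialogue(BaseModel):
    """One scenario-level examiner-patient exchange."""

    model_config = ConfigDict(frozen=True)

    subject_id: str
    scenario_id: str
    utterances: tuple[Utterance, ...]
    truth: Optional[TruthAnnotation] = None

    @field_validator("scenario_id")
    @classmethod
    def _scenario(cls, v: str) -> str:
        return canonical_scenario(v)

    @model_validator(mode="after")
    def _consecutive_indices(self) -> "DiarizedDialogue":
        indices = [u.index for u in self.utterances]
        if indices != list(range(len(indices))):
            raise ValueError("utterance indices must be consecutive from 0")
        return self

    def patient_utterances(self) -> list[Utterance]:
        return [u for u in self.utterances if u.speaker == "patient"]


class SubjectRecord(BaseModel):
    """All dialogues of one subject plus an optional A4 ground-truth score."""

    model_config = ConfigDict(frozen=True)

    subject_id: str
    dialogues: tuple[DiarizedDialogue, ...]
    a4_score: Optional[int] = None

    @field_validator("a4_score")
    @classmethod
    def _score_range(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v not in (0, 1, 2, 3):
            raise ValueError("a4_score must be in 0..3")
        return v

    @model_validator(mode="after")
    def _unique_scenarios(self) -> "SubjectRecord":
        seen = set()
        for d in self.dialogues:
            if d.subject_id != self.subject_id:
                raise ValueError("dialogue subject_id does not match record")
            if d.scenario_id in seen:
                raise ValueError(f"duplicate dialogue for scenario {d.scenario_id}")
            seen.add(d.scenario_id)
        return self


def truth_sidecar_path(path: str | Path) -> Path:
    """Sidecar location for a transcript: ``corpus.jsonl`` -> ``corpus.truth.jsonl``."""
    p = Path(path)
    return p.with_name(p.stem + ".truth.jsonl")


def _escape_tsv(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape_tsv(text: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            if nxt == "t":
                out.append("\t")
                i += 2
                continue
            if nxt == "n":
                out.append("\n")
                i += 2
                continue
            if nxt == "\\":
                out.append("\\")
                i += 2
                continue
        out.append(c)
        i += 1
    return "".join(out)


def _parse_speaker(token: str, line: int) -> str:
    role = _SPEAKER_ALIASES.get(str(token).strip().lower())
    if role is None:
        raise CorpusParseError(
            f"unknown speaker role {token!r} (expected examiner/E or patient/P)", line
        )
    return role


def _iter_raw_rows(path: Path, dialect: Dialect):
    """Yield (line_number, row_dict) for both dialects."""
    with path.open("r", encoding="utf-8") as fh:
        if dialect == "jsonl":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusParseError(f"invalid JSON: {exc.msg}", lineno) from exc
                if not isinstance(obj, dict):
                    raise CorpusParseError("record must be a JSON object", lineno)
                yield lineno, obj
        elif dialect == "tsv":
            header: list[str] | None = None
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                cells = line.split("\t")
                if header is None:
                    header = cells
                    expected = ["subject_id", "scenario_id", "index", "speaker", "text"]
                    if header != expected:
                        raise CorpusParseError(f"bad TSV header {header!r}", lineno)
                    continue
                if len(cells) != len(header):
                    raise CorpusParseError(f"expected {len(header)} columns, got {len(cells)}", lineno)
                row = dict(zip(header, cells))
                row["text"] = _unescape_tsv(row["text"])
                yield lineno, row
        else:
            raise CorpusParseError(f"unknown dialect {dialect!r}")


def _read_truth_sidecar(path: Path):
    """Return (per-dialogue truth map, per-subject a4 map)."""
    truths: dict[tuple[str, str], TruthAnnotation] = {}
    a4: dict[str, int] = {}
    if not path.exists():
        return truths, a4
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"invalid truth JSON: {exc.msg}", lineno) from exc
            subject = str(obj["subject_id"])
            if "scenario_id" in obj and obj["scenario_id"] is not None:
                key = (subject, canonical_scenario(obj["scenario_id"]))
                truths[key] = TruthAnnotation(
                    profile=FeatureProfile(presence=tuple(obj["profile"])),
                    label=int(obj["label"]),
                    planted={k: tuple(v) for k, v in obj.get("planted", {}).items()},
                )
            else:
                a4[subject] = int(obj["a4_score"])
    return truths, a4


def read_corpus(path: str | Path, dialect: Dialect = "jsonl") -> list[SubjectRecord]:
    """Read a transcript file (plus truth sidecar, if present) into records.

    Utterances are grouped by (subject, scenario), ordered by index, and
    validated: unknown scenario tokens, unknown speaker roles and duplicate
    (subject, scenario, index) triples are rejected with the offending line
    number.
    """
    path = Path(path)
    # key -> {index: (lineno, Utterance)}
    grouped: dict[tuple[str, str], dict[int, Utterance]] = {}
    subject_order: list[str] = []
    dialogue_order: dict[str, list[str]] = {}

    for lineno, row in _iter_raw_rows(path, dialect):
        try:
            subject = str(row["subject_id"])
            scenario = canonical_scenario(row["scenario_id"])
            index = int(row["index"])
            speaker = _parse_speaker(row["speaker"], lineno)
            utt = Utterance(index=index, speaker=speaker, text=str(row["text"]))
        except CorpusParseError:
            raise
        except KeyError as exc:
            raise CorpusParseError(f"missing field {exc.args[0]!r}", lineno) from exc
        except Exception as exc:
            raise CorpusParseError(str(exc), lineno) from exc

        key = (subject, scenario)
        if key not in grouped:
            grouped[key] = {}
            if subject not in dialogue_order:
                subject_order.append(subject)
                dialogue_order[subject] = []
            dialogue_order[subject].append(scenario)
        if index in grouped[key]:
            raise DuplicateUtteranceError(
                f"duplicate utterance index {index} for subject {subject!r}, scenario {scenario}",
                lineno,
            )
        grouped[key][index] = utt

    truths, a4 = _read_truth_sidecar(truth_sidecar_path(path))

    records: list[SubjectRecord] = []
    for subject in subject_order:
        dialogues = []
        for scenario in dialogue_order[subject]:
            utts = grouped[(subject, scenario)]
            ordered = [utts[i] for i in sorted(utts)]
            if sorted(utts) != list(range(len(utts))):
                raise CorpusParseError(
                    f"utterance indices for subject {subject!r}, scenario {scenario} "
                    f"are not consecutive from 0: {sorted(utts)}"
                )
            dialogues.append(
                DiarizedDialogue(
                    subject_id=subject,
                    scenario_id=scenario,
                    utterances=tuple(ordered),
                    truth=truths.get((subject, scenario)),
                )
            )
        records.append(
            SubjectRecord(subject_id=subject, dialogues=tuple(dialogues), a4_score=a4.get(subject))
        )
    return records


def write_corpus(records: Iterable[SubjectRecord], path: str | Path, dialect: Dialect = "jsonl") -> None:
    """Write records to a transcript file; truth annotations go to the sidecar."""
    path = Path(path)
    records = list(records)
    truth_lines: list[str] = []

    with path.open("w", encoding="utf-8") as fh:
        if dialect == "tsv":
            fh.write("subject_id\tscenario_id\tindex\tspeaker\ttext\n")
        for rec in records:
            for dlg in rec.dialogues:
                for utt in dlg.utterances:
                    if dialect == "jsonl":
                        fh.write(
                            json.dumps(
                                {
                                    "subject_id": rec.subject_id,
                                    "scenario_id": dlg.scenario_id,
                                    "index": utt.index,
                                    "speaker": utt.speaker,
                                    "text": utt.text,
                                },
                                ensure_ascii=False,
                            )
                            + "\n"
                        )
                    elif dialect == "tsv":
                        fh.write(
                            "\t".join(
                                [
                                    rec.subject_id,
                                    dlg.scenario_id,
                                    str(utt.index),
                                    utt.speaker,
                                    _escape_tsv(utt.text),
                                ]
                            )
                            + "\n"
                        )
                    else:
                        raise CorpusParseError(f"unknown dialect {dialect!r}")
                if dlg.truth is not None:
                    truth_lines.append(
                        json.dumps(
                            {
                                "subject_id": rec.subject_id,
                                "scenario_id": dlg.scenario_id,
                                "profile": list(dlg.truth.profile.presence),
                                "label": dlg.truth.label,
                                "planted": {k: list(v) for k, v in dlg.truth.planted.items()},
                            },
                            ensure_ascii=False,
                        )
                    )
            if rec.a4_score is not None:
                truth_lines.append(
                    json.dumps({"subject_id": rec.subject_id, "a4_score": rec.a4_score})
                )

    sidecar = truth_sidecar_path(path)
    if truth_lines:
        sidecar.write_text("\n".join(truth_lines) + "\n", encoding="utf-8")
    elif sidecar.exists():
        sidecar.unlink()


def filter_included(records: Iterable[SubjectRecord]) -> list[SubjectRecord]:
    """Restrict every record to the 11 included (dialogic) scenarios.

    Subjects left with zero dialogues are dropped, with a warning naming them.
    Idempotent.
    """
    keep = set(included_scenarios())
    out: list[SubjectRecord] = []
    dropped: list[str] = []
    for rec in records:
        dialogues = tuple(d for d in rec.dialogues if d.scenario_id in keep)
        if not dialogues:
            dropped.append(rec.subject_id)
            continue
        out.append(
            SubjectRecord(subject_id=rec.subject_id, dialogues=dialogues, a4_score=rec.a4_score)
        )
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} subject(s) with no included-scenario dialogues: {dropped}",
            stacklevel=2,
        )
    return out
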