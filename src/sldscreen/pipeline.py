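"""End-to-end screening: dialogues -> prompts -> detector -> verdicts -> diagnoses."""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

from .classify import ScenarioVerdict, SubjectDiagnosis, classify_corpus
from .detector import DetectorBackend, ReferenceBackend, detect
from .dialogue import SubjectRecord
from .parsing import AmbiguityPolicy, verdict_from_response
from .prompts import build_diagnosis_prompt, build_feature_prompt

__all__ = ["scenario_verdicts", "screen_corpus"]


def scenario_verdicts(
    records: Iterable[SubjectRecord],
    backend: DetectorBackend | None = None,
    kind: Literal["diagnosis", "feature_extraction"] = "feature_extraction",
    policy: AmbiguityPolicy = "error",
) -> list[ScenarioVerdict]:
    """Run one prompt per dialogue through a backend and parse the answers."""
    backend = backend or ReferenceBackend()
    build = build_diagnosis_prompt if kind == "diagnosis" else build_feature_prompt
    verdicts = []
    for rec in records:
        for dlg in rec.dialogues:
            response = detect(build(dlg), backend)
            verdicts.append(verdict_from_response(response, policy))
    return verdicts


def screen_corpus(
    records: Sequence[SubjectRecord],
    backend: DetectorBackend | None = None,
    policy: AmbiguityPolicy = "error",
    critical_set: Iterable[str] | None = None,
    cumulative_threshold: int = 2,
) -> tuple[list[ScenarioVerdict], list[SubjectDiagnosis]]:
    """Feature-extraction screening of a whole corpus.

    Returns the per-dialogue verdicts and the rule-classified, OR-aggregated
    subject diagnoses.
    """
    verdicts = scenario_verdicts(records, backend, "feature_extraction", policy)
    diagnoses = classify_corpus(verdicts, critical_set, cumulative_threshold)
    return verdicts, diagnoses
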