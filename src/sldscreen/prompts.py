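"""Structured prompt construction for the two screening questions.

Two prompts are built from a diarized dialogue:

* the *diagnosis* prompt — the rendered examiner-patient dialogue (EPD)
  followed by a fixed yes/no question about observed social language
  disorders (SLDs);
* the *feature-extraction* prompt — the EPD, a question asking which of the
  ten deficit features are observed, and a knowledge block listing every
  feature as ``F<k> (<name>): <explanation>``.

Prompt rendering is a pure function of (dialogue, taxonomy): no hidden
state, timestamps or randomness. The templates are packaged text files with
a two-placeholder syntax (``{{dialogue}}``, ``{{question}}``,
``{{knowledge}}``) so the wording can be tuned for live LLM use without
touching logic.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Literal, Sequence

from pydantic import BaseModel, ConfigDict

from .dialogue import DiarizedDialogue
from .errors import EmptyDialogueError, KnowledgeError
from .knowledge import FEATURE_IDS, FeatureDefinition, load_feature_taxonomy

__all__ = [
    "DIAGNOSIS_QUESTION",
    "FEATURE_QUESTION",
    "KNOWLEDGE_HEADER",
    "PromptBundle",
    "render_dialogue_text",
    "build_diagnosis_prompt",
    "build_feature_prompt",
]

#: The verbatim yes/no screening question. Single constant; every diagnosis
#: prompt embeds exactly this string.
DIAGNOSIS_QUESTION = (
    "Based on the above conversation between the examiner and the patient, "
    "please categorize if any observed SLDs for the patient. "
    "Answer only 'Yes' or 'No'."
)

#: The multi-label question. The answer contract (comma-separated feature
#: IDs, or 'None') keeps the response parser well defined.
FEATURE_QUESTION = (
    "Based on the above conversation between the examiner and the patient, "
    "identify which of the 10 features of social language disorders listed "
    "below are observed for the patient. Answer only with the comma-separated "
    "feature IDs that are present (for example: F1, F9), or 'None'."
)

KNOWLEDGE_HEADER = (
    "Overview of the 10 features of social language disorders identified by "
    "ADOS-2 examiners:"
)

_SHORT_PREFIX = {"examiner": "E", "patient": "P"}
_LONG_PREFIX = {"examiner": "Examiner", "patient": "Patient"}


class PromptBundle(BaseModel):
    """A fully rendered prompt plus its provenance."""

    model_config = ConfigDict(frozen=True)

    kind: Literal["diagnosis", "feature_extraction"]
    text: str
    dialogue_ref: tuple[str, str]  # (subject_id, scenario_id)


@lru_cache(maxsize=None)
def _template(name: str) -> str:
    path = resources.files("sldscreen.data.templates").joinpath(f"{name}.txt")
    return path.read_text(encoding="utf-8").rstrip("\n")


def render_dialogue_text(
    dialogue: DiarizedDialogue, role_style: Literal["short", "long"] = "short"
) -> str:
    """Render one utterance per line, prefixed ``E: `` / ``P: ``, in order.

    Lossless with respect to utterance text (utterances are already
    whitespace-normalized, so they contain no newlines of their own).
    """
    if not dialogue.utterances:
        raise EmptyDialogueError(
            f"dialogue {dialogue.subject_id}/{dialogue.scenario_id} has no utterances"
        )
    prefix = _SHORT_PREFIX if role_style == "short" else _LONG_PREFIX
    lines = [
        f"{prefix[u.speaker]}: {u.text.replace(chr(10), ' ')}" for u in dialogue.utterances
    ]
    return "\n".join(lines)


def build_diagnosis_prompt(
    dialogue: DiarizedDialogue, role_style: Literal["short", "long"] = "short"
) -> PromptBundle:
    """EPD + blank line + the verbatim yes/no question."""
    text = (
        _template("diagnosis")
        .replace("{{dialogue}}", render_dialogue_text(dialogue, role_style))
        .replace("{{question}}", DIAGNOSIS_QUESTION)
    )
    return PromptBundle(
        kind="diagnosis", text=text, dialogue_ref=(dialogue.subject_id, dialogue.scenario_id)
    )


def _knowledge_block(taxonomy: Sequence[FeatureDefinition]) -> str:
    ids = [f.id for f in taxonomy]
    if ids != list(FEATURE_IDS):
        raise KnowledgeError(f"taxonomy must list F1..F10 in order, got {ids}")
    entries = [f"{f.id} ({f.name}): {f.explanation}" for f in taxonomy]
    return "\n".join([KNOWLEDGE_HEADER, *entries])


def build_feature_prompt(
    dialogue: DiarizedDialogue,
    taxonomy: Sequence[FeatureDefinition] | None = None,
    role_style: Literal["short", "long"] = "short",
) -> PromptBundle:
    """EPD + feature question + knowledge block over the full taxonomy."""
    if taxonomy is None:
        taxonomy = load_feature_taxonomy()
    text = (
        _template("features")
        .replace("{{dialogue}}", render_dialogue_text(dialogue, role_style))
        .replace("{{question}}", FEATURE_QUESTION)
        .replace("{{knowledge}}", _knowledge_block(taxonomy))
    )
    return PromptBundle(
        kind="feature_extraction",
        text=text,
        dialogue_ref=(dialogue.subject_id, dialogue.scenario_id),
    )
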