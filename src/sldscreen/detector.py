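"""Pluggable detectors: a deterministic reference detector and live adapters.

The *reference detector* is a pure, deterministic operationalization of the
ten feature definitions as surface rules over patient utterances (echo
matching, lexicon hits, pronoun-frame patterns). It is **not** a claim about
clinical validity: it exists so the whole pipeline has an offline oracle that
is exactly aligned with the synthetic generator's injectors, making every
downstream stage testable without an LLM API. Lexicons are packaged data
files and user-extensible.

Live adapters (OpenAI, Gemini) implement the same one-call interface with
temperature-0 defaults; they import their SDKs lazily and are excluded from
the offline test surface.
"""

from __future__ import annotations

import re
from typing import Protocol, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict
from sklearn.base import BaseEstimator, TransformerMixin

from .dialogue import DiarizedDialogue, Utterance
from .errors import BackendError, CorpusParseError
from .knowledge import FEATURE_IDS
from .lexicons import (
    FLAT_TONE_MARKER,
    contains_phrase,
    normalize_for_match,
    normalized_lexicon,
    tokens_for_match,
)
from .profiles import FeatureProfile
from .prompts import PromptBundle

__all__ = [
    "DetectorResponse",
    "DetectorBackend",
    "ReferenceBackend",
    "OpenAIBackend",
    "GeminiBackend",
    "FeatureRuleDetector",
    "reference_feature_rules",
    "detect",
]

#: Minimum normalized-token length for the echo rule, so that trivial
#: affirmation echoes ("Yeah") are not flagged as echoic repetition.
DEFAULT_ECHO_MIN_TOKENS = 5

_PRONOUN_FRAME = re.compile(r"\b(?:you|he|she)\s+(?:wants?|needs?|likes?)\b")
_QUOTE_SPAN = re.compile(r"[\"“][^\"“”]{3,}[\"”]")

#: Person-deictic words collapse to one placeholder before echo comparison:
#: an echo typically flips first/second person ("Do you have some friends?"
#: -> "do I have some friends?") and still counts as echoic repetition.
_DEICTIC = {"i", "you", "we", "me", "my", "your", "our", "mine", "yours", "ours"}

#: Leading discourse fillers are ignored on both sides of an echo
#: comparison ("Uh, do I have some friends?" echoes "Okay. So, do you have
#: some friends?").
_LEADING_FILLERS = {"uh", "um", "er", "hmm", "well", "okay", "ok", "so", "oh"}


def _echo_tokens(text: str) -> list[str]:
    toks = tokens_for_match(text)
    start = 0
    while start < len(toks) and toks[start] in _LEADING_FILLERS:
        start += 1
    return ["_p_" if t in _DEICTIC else t for t in toks[start:]]


class DetectorResponse(BaseModel):
    """A backend's verbatim answer to one prompt."""

    model_config = ConfigDict(frozen=True)

    raw_text: str
    prompt_ref: tuple[str, str, str]  # (subject_id, scenario_id, kind)


class DetectorBackend(Protocol):
    """One-call detector interface: a prompt in, a raw answer string out."""

    def complete(self, prompt: PromptBundle) -> str:  # pragma: no cover - protocol
        ...


def reference_feature_rules(
    dialogue: DiarizedDialogue, echo_min_tokens: int = DEFAULT_ECHO_MIN_TOKENS
) -> FeatureProfile:
    """Apply the deterministic per-feature surface rules to one dialogue.

    Rules (patient utterances only):

    * F1 — a patient utterance whose normalized text equals, or is a
      >= ``echo_min_tokens``-token prefix/suffix of, the immediately
      preceding examiner utterance;
    * F2 — odd-content lexicon hit;
    * F3 — a second/third-person pronoun in a self-reference frame
      ("you/he/she want(s)/need(s)/like(s)");
    * F4 — a joke marker in the same utterance as a serious-topic keyword;
    * F5 — archaic/formal lexicon hit;
    * F6 — filler-tag lexicon hit;
    * F7 — courtesy-phrase hit outside a gratitude-eliciting examiner turn;
    * F8 — flat-intonation marker token, or the same social phrase repeated
      at least twice across patient utterances;
    * F9 — a quote-marker-wrapped span, or a media-quote lexicon hit;
    * F10 — cliche lexicon hit.
    """
    odd = normalized_lexicon("odd_content")
    archaic = normalized_lexicon("archaic_formal")
    fillers = normalized_lexicon("fillers")
    courtesy = normalized_lexicon("courtesy")
    gratitude = normalized_lexicon("gratitude_cues")
    social = normalized_lexicon("social_phrases")
    media = normalized_lexicon("media_quotes")
    cliches = normalized_lexicon("cliches")
    jokes = normalized_lexicon("joke_markers")
    serious = normalized_lexicon("serious_topics")
    flat_marker = normalize_for_match(FLAT_TONE_MARKER)

    present: set[str] = set()
    social_counts: dict[str, int] = {}
    prev_examiner_norm: str | None = None

    utterances: Sequence[Utterance] = dialogue.utterances
    for pos, utt in enumerate(utterances):
        if utt.speaker == "examiner":
            prev_examiner_norm = normalize_for_match(utt.text)
            continue

        norm = normalize_for_match(utt.text)
        toks = norm.split()
        padded = f" {norm} "

        # F1: echo of the utterance immediately before this one (comparison
        # is pronoun-insensitive and ignores leading discourse fillers, so
        # person-flipped echoes like "do I have some friends?" still match).
        if pos > 0 and utterances[pos - 1].speaker == "examiner":
            pt = _echo_tokens(utt.text)
            et = _echo_tokens(utterances[pos - 1].text)
            if len(pt) >= echo_min_tokens and (
                pt == et or pt == et[: len(pt)] or pt == et[-len(pt):]
            ):
                present.add("F1")

        if contains_phrase(norm, odd):
            present.add("F2")
        if _PRONOUN_FRAME.search(norm):
            present.add("F3")
        if contains_phrase(norm, jokes) and contains_phrase(norm, serious):
            present.add("F4")
        if contains_phrase(norm, archaic):
            present.add("F5")
        if contains_phrase(norm, fillers):
            present.add("F6")
        if contains_phrase(norm, courtesy):
            eliciting = prev_examiner_norm is not None and contains_phrase(
                prev_examiner_norm, gratitude
            )
            if not eliciting:
                present.add("F7")
        if f" {flat_marker} " in padded:
            present.add("F8")
        for phrase in social:
            # lookahead count so repeats that abut are all seen
            n_occ = len(re.findall(rf"(?=(?:^| ){re.escape(phrase)}(?: |$))", norm))
            if n_occ:
                social_counts[phrase] = social_counts.get(phrase, 0) + n_occ
        if _QUOTE_SPAN.search(utt.text) or contains_phrase(norm, media):
            present.add("F9")
        if contains_phrase(norm, cliches):
            present.add("F10")

    if any(c >= 2 for c in social_counts.values()):
        present.add("F8")

    return FeatureProfile.from_features(present)


class FeatureRuleDetector(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer mapping dialogues to a binary feature matrix.

    ``transform`` takes a sequence of :class:`DiarizedDialogue` and returns an
    ``(n_dialogues, 10)`` integer array in F1..F10 column order. The rules are
    stateless, so ``fit`` only records the feature names.

    Parameters
    ----------
    echo_min_tokens : int, default=5
        Minimum normalized-token length for the F1 echo rule.
    """

    def __init__(self, echo_min_tokens: int = DEFAULT_ECHO_MIN_TOKENS):
        self.echo_min_tokens = echo_min_tokens

    def fit(self, X: Sequence[DiarizedDialogue], y=None) -> "FeatureRuleDetector":
        self.feature_names_ = list(FEATURE_IDS)
        return self

    def transform(self, X: Sequence[DiarizedDialogue]) -> np.ndarray:
        return np.array(
            [
                reference_feature_rules(d, echo_min_tokens=self.echo_min_tokens).as_array()
                for d in X
            ],
            dtype=int,
        ).reshape(len(list(X)), len(FEATURE_IDS))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_IDS, dtype=object)


_EPD_LINE = re.compile(r"^(E|P|Examiner|Patient): (.*)$")


def _dialogue_from_prompt(prompt: PromptBundle) -> DiarizedDialogue:
    """Reconstruct the EPD block of a prompt into a dialogue.

    The reference backend consumes only the prompt text (like a live model
    would), so the EPD lines are parsed back out of it.
    """
    utterances: list[Utterance] = []
    for line in prompt.text.splitlines():
        m = _EPD_LINE.match(line)
        if not m:
            continue
        role = "examiner" if m.group(1) in ("E", "Examiner") else "patient"
        utterances.append(Utterance(index=len(utterances), speaker=role, text=m.group(2)))
    if not utterances:
        raise CorpusParseError("prompt contains no EPD lines to analyze")
    subject, scenario = prompt.dialogue_ref
    return DiarizedDialogue(
        subject_id=subject, scenario_id=scenario, utterances=tuple(utterances)
    )


class ReferenceBackend:
    """Deterministic offline backend driven by the reference feature rules.

    Its diagnosis answer is "Yes" exactly when its own feature rules yield a
    non-empty profile, so the two prompt kinds are internally consistent.
    """

    def __init__(self, echo_min_tokens: int = DEFAULT_ECHO_MIN_TOKENS):
        self.echo_min_tokens = echo_min_tokens

    def complete(self, prompt: PromptBundle) -> str:
        dialogue = _dialogue_from_prompt(prompt)
        profile = reference_feature_rules(dialogue, echo_min_tokens=self.echo_min_tokens)
        features = sorted(profile.to_features(), key=lambda f: int(f[1:]))
        if prompt.kind == "diagnosis":
            return "Yes" if features else "No"
        return ", ".join(features) if features else "None"


class OpenAIBackend:
    """Thin adapter for OpenAI chat models (interface only; needs the SDK)."""

    def __init__(self, model: str = "gpt-3.5-turbo", temperature: float = 0.0, max_retries: int = 2):
        self.model = model
        self.temperature = temperature
        self.max_retries = max_retries

    def complete(self, prompt: PromptBundle) -> str:  # pragma: no cover - live API
        try:
            from openai import OpenAI
        except ImportError as exc:
            raise BackendError(
                "the 'openai' SDK is not installed; install it to use OpenAIBackend",
                retryable=False,
            ) from exc
        client = OpenAI()
        last: Exception | None = None
        for attempt in range(1, self.max_retries + 1):
            try:
                resp = client.chat.completions.create(
                    model=self.model,
                    temperature=self.temperature,
                    messages=[{"role": "user", "content": prompt.text}],
                )
                return resp.choices[0].message.content or ""
            except Exception as exc:  # transport failure
                last = exc
        raise BackendError(f"OpenAI request failed: {last}", retryable=True, attempts=self.max_retries)


class GeminiBackend:
    """Thin adapter for Google Gemini models (interface only; needs the SDK)."""

    def __init__(self, model: str = "gemini-1.5-flash", temperature: float = 0.0, max_retries: int = 2):
        self.model = model
        self.temperature = temperature
        self.max_retries = max_retries

    def complete(self, prompt: PromptBundle) -> str:  # pragma: no cover - live API
        try:
            import google.generativeai as genai
        except ImportError as exc:
            raise BackendError(
                "the 'google-generativeai' SDK is not installed; install it to use GeminiBackend",
                retryable=False,
            ) from exc
        model = genai.GenerativeModel(self.model)
        last: Exception | None = None
        for attempt in range(1, self.max_retries + 1):
            try:
                resp = model.generate_content(
                    prompt.text, generation_config={"temperature": self.temperature}
                )
                return resp.text
            except Exception as exc:
                last = exc
        raise BackendError(f"Gemini request failed: {last}", retryable=True, attempts=self.max_retries)


def detect(prompt: PromptBundle, backend: DetectorBackend) -> DetectorResponse:
    """Run one prompt through a backend and wrap the verbatim answer."""
    raw = backend.complete(prompt)
    if raw is None:
        raise BackendError("backend returned no text")
    return DetectorResponse(raw_text=raw, prompt_ref=(*prompt.dialogue_ref, prompt.kind))


def make_backend(name: str, **kwargs) -> DetectorBackend:
    """Backend factory keyed by config token: reference | openai | gemini."""
    if name == "reference":
        return ReferenceBackend(**kwargs)
    if name == "openai":
        return OpenAIBackend(**kwargs)
    if name == "gemini":
        return GeminiBackend(**kwargs)
    raise BackendError(f"unknown backend {name!r}; expected reference, openai or gemini")
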