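"""Parsing raw detector answers into structured verdicts.

Two answer kinds are parsed: the yes/no screening decision and the
multi-label feature list. Ambiguity handling is explicit: the default
policy fails loudly (silent coercion would corrupt downstream metrics),
and an opt-in pessimistic policy maps ambiguous answers to the negative
outcome with a logged warning.
"""

from __future__ import annotations

import re
import warnings
from typing import Literal

from .classify import ScenarioVerdict, classify_scenario
from .detector import DetectorResponse
from .errors import AmbiguousResponseError, UnknownFeatureError
from .knowledge import FEATURE_IDS, feature_names

__all__ = ["parse_diagnosis", "parse_features", "verdict_from_response"]

AmbiguityPolicy = Literal["error", "pessimistic-no"]

_YES = re.compile(r"(?<![a-z0-9])yes(?![a-z0-9])", re.IGNORECASE)
_NO = re.compile(r"(?<![a-z0-9])no(?![a-z0-9])", re.IGNORECASE)
_FEATURE_TOKEN = re.compile(r"(?<![a-z0-9])f\s?(\d+)(?![0-9])", re.IGNORECASE)
_NONE_TOKEN = re.compile(r"(?<![a-z0-9])none(?![a-z0-9])", re.IGNORECASE)


def _ambiguous(message: str, policy: AmbiguityPolicy, fallback):
    if policy == "error":
        raise AmbiguousResponseError(message)
    warnings.warn(f"{message}; falling back to the negative outcome", stacklevel=3)
    return fallback


def parse_diagnosis(raw_text: str, policy: AmbiguityPolicy = "error") -> bool:
    """Parse a yes/no screening answer.

    Scans case-insensitively for a standalone "yes"/"no" token, tolerating
    surrounding punctuation. Finding neither token, both tokens, or an
    empty answer is ambiguous.
    """
    has_yes = bool(_YES.search(raw_text))
    has_no = bool(_NO.search(raw_text))
    if has_yes and not has_no:
        return True
    if has_no and not has_yes:
        return False
    if has_yes and has_no:
        return _ambiguous(f"answer contains both 'Yes' and 'No': {raw_text!r}", policy, False)
    return _ambiguous(f"answer contains neither 'Yes' nor 'No': {raw_text!r}", policy, False)


def parse_features(raw_text: str, policy: AmbiguityPolicy = "error") -> set[str]:
    """Parse a multi-label feature answer into a set of feature IDs.

    Matches ``F<k>`` tokens (k in 1..10) and full feature names from the
    taxonomy, case-insensitively; duplicates collapse. A standalone "None"
    with no feature token yields the empty set. ``F<k>`` outside 1..10 is an
    unknown-feature error; an answer with no token at all is ambiguous.
    """
    found: set[str] = set()
    for m in _FEATURE_TOKEN.finditer(raw_text):
        k = int(m.group(1))
        if not 1 <= k <= len(FEATURE_IDS):
            raise UnknownFeatureError(f"feature token F{k} outside F1..F{len(FEATURE_IDS)}")
        found.add(f"F{k}")
    lowered = raw_text.lower()
    for fid, name in feature_names().items():
        if name.lower() in lowered:
            found.add(fid)
    if found:
        return found
    if _NONE_TOKEN.search(raw_text):
        return set()
    return _ambiguous(f"answer contains no feature token or 'None': {raw_text!r}", policy, set())


def verdict_from_response(
    response: DetectorResponse, policy: AmbiguityPolicy = "error"
) -> ScenarioVerdict:
    """Turn one raw detector response into a scenario verdict.

    Diagnosis answers set ``sld_present`` directly (no feature evidence);
    feature answers set the feature set, with ``sld_present`` derived from
    the default A4 rules.
    """
    subject_id, scenario_id, kind = response.prompt_ref
    if kind == "diagnosis":
        present = parse_diagnosis(response.raw_text, policy)
        features: frozenset[str] = frozenset()
    else:
        features = frozenset(parse_features(response.raw_text, policy))
        present = bool(classify_scenario(features)[0])
    return ScenarioVerdict(
        subject_id=subject_id,
        scenario_id=scenario_id,
        sld_present=present,
        features=features,
        raw_ref=response.prompt_ref,
    )
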