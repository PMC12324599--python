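"""Fixed domain knowledge for ADOS-2 Module 4 language screening.

This module exposes the three constant knowledge artifacts the pipeline is
built on:

* the ten-feature taxonomy of unconventional language patterns (F1..F10),
  with the prose explanations that are injected verbatim into the
  feature-extraction prompt;
* the Module 4 scenario catalog (S1..S15) with the inclusion rule that keeps
  the 11 dialogic, social-language scenarios and drops the construction,
  story-from-book, demonstration and break tasks;
* the A4 item rubric ("Stereotyped/Idiosyncratic Use of Words or Phrases",
  ordinal 0-3) and its binarization (0 vs >0) used for diagnosis labels.

All three ship as human-readable TSV files under ``sldscreen/data`` and are
immutable: loading twice yields identical content.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .errors import InvalidScoreError, KnowledgeError

__all__ = [
    "FeatureDefinition",
    "ScenarioDefinition",
    "A4Rubric",
    "FEATURE_IDS",
    "SCENARIO_IDS",
    "DEFAULT_CRITICAL",
    "load_feature_taxonomy",
    "feature_names",
    "load_scenario_catalog",
    "included_scenarios",
    "canonical_scenario",
    "load_a4_rubric",
    "a4_to_label",
    "default_prevalence_table",
]

#: The ten feature identifiers, in canonical order.
FEATURE_IDS: tuple[str, ...] = tuple(f"F{k}" for k in range(1, 11))

#: The fifteen Module 4 scenario identifiers.
SCENARIO_IDS: tuple[str, ...] = tuple(f"S{k}" for k in range(1, 16))

#: Features treated as severe on their own ("critical") by default.
#: Only echoic repetition (F1) and stereotyped media quoting (F9) are ever
#: named as critical in the rubric; the set is a configuration knob of the
#: rule classifier, not hard-wired.
DEFAULT_CRITICAL: frozenset[str] = frozenset({"F1", "F9"})


class FeatureDefinition(BaseModel):
    """One of the ten linguistic-deficit features."""

    model_config = ConfigDict(frozen=True)

    id: str
    name: str
    explanation: str
    critical: bool


class ScenarioDefinition(BaseModel):
    """One of the fifteen Module 4 scenario tasks."""

    model_config = ConfigDict(frozen=True)

    id: str
    name: str
    dialogic: bool
    included: bool


class A4Rubric(BaseModel):
    """The four-level A4 scoring rubric."""

    model_config = ConfigDict(frozen=True)

    levels: dict[int, str]


def _read_tsv(filename: str) -> list[dict[str, str]]:
    path = resources.files("sldscreen.data").joinpath(filename)
    with path.open("r", encoding="utf-8", newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


@lru_cache(maxsize=None)
def _taxonomy_rows() -> tuple[tuple[str, str, str, bool], ...]:
    rows = _read_tsv("feature_taxonomy.tsv")
    if [r["id"] for r in rows] != list(FEATURE_IDS):
        raise KnowledgeError("feature taxonomy must list F1..F10 exactly once, in order")
    return tuple((r["id"], r["name"], r["explanation"], r["critical"] == "1") for r in rows)


def load_feature_taxonomy(critical: frozenset[str] | set[str] | None = None) -> list[FeatureDefinition]:
    """Return the ten feature definitions in F1..F10 order.

    Parameters
    ----------
    critical
        Override for the critical-feature set. ``None`` keeps the packaged
        default ({F1, F9}).
    """
    if critical is not None:
        unknown = set(critical) - set(FEATURE_IDS)
        if unknown:
            raise KnowledgeError(f"unknown critical features: {sorted(unknown)}")
    return [
        FeatureDefinition(
            id=fid,
            name=name,
            explanation=expl,
            critical=(fid in critical) if critical is not None else crit,
        )
        for fid, name, expl, crit in _taxonomy_rows()
    ]


def feature_names() -> dict[str, str]:
    """Mapping feature id -> short label, e.g. ``{"F1": "Echoic Repetition", ...}``."""
    return {f.id: f.name for f in load_feature_taxonomy()}


@lru_cache(maxsize=None)
def load_scenario_catalog() -> tuple[ScenarioDefinition, ...]:
    """Return all fifteen scenario definitions in S1..S15 order."""
    rows = _read_tsv("scenario_catalog.tsv")
    if [r["id"] for r in rows] != list(SCENARIO_IDS):
        raise KnowledgeError("scenario catalog must list S1..S15 exactly once, in order")
    return tuple(
        ScenarioDefinition(
            id=r["id"], name=r["name"], dialogic=r["dialogic"] == "1", included=r["included"] == "1"
        )
        for r in rows
    )


def included_scenarios() -> list[str]:
    """The 11 dialogic scenarios retained for analysis, ascending by number."""
    return [s.id for s in load_scenario_catalog() if s.included]


def canonical_scenario(token: str | int) -> str:
    """Canonicalize a scenario token: ``3``, ``"3"``, ``"s3"`` -> ``"S3"``.

    Bare integers appear as row labels in the per-scenario prevalence table
    and are mapped onto the canonical ``S``-prefixed tokens on read.
    """
    s = str(token).strip().upper()
    if not s.startswith("S"):
        s = "S" + s
    if s not in SCENARIO_IDS:
        raise KnowledgeError(f"unknown scenario token: {token!r}")
    return s


@lru_cache(maxsize=None)
def load_a4_rubric() -> A4Rubric:
    """The four-level A4 rubric (scores 0-3 with prose descriptions)."""
    rows = _read_tsv("a4_rubric.tsv")
    levels = {int(r["score"]): r["description"] for r in rows}
    if sorted(levels) != [0, 1, 2, 3]:
        raise KnowledgeError("A4 rubric must define exactly scores 0,1,2,3")
    return A4Rubric(levels=levels)


def a4_to_label(score: int) -> int:
    """Binarize an A4 score: 0 -> label 0, any of {1,2,3} -> label 1."""
    if not isinstance(score, int) or isinstance(score, bool) or score not in (0, 1, 2, 3):
        raise InvalidScoreError(f"A4 score must be an integer in 0..3, got {score!r}")
    return int(score > 0)


@lru_cache(maxsize=None)
def _default_prevalence() -> pd.DataFrame:
    path = resources.files("sldscreen.data").joinpath("prevalence_default.csv")
    with path.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, index_col="scenario")
    df.index = [canonical_scenario(s) for s in df.index]
    df.index.name = "scenario"
    return df


def default_prevalence_table() -> pd.DataFrame:
    """Default per-(scenario, feature) planting probabilities.

    Rows are the 11 included scenarios, columns F1..F10, values in [0, 1].
    The excluded scenarios (S1, S2, S8, S10) have no default row; generating
    them requires user-supplied prevalences.
    """
    return _default_prevalence().copy()
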