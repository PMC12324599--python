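"""Synthetic examiner-patient dialogue corpus with planted deficit features.

The generator emulates scenario-segmented ADOS-2 Module 4 exchanges in which
the ten linguistic-deficit features are planted at configurable
per-(scenario, feature) prevalences with controllable pairwise co-occurrence,
so every downstream stage is testable without access to real clinical data.

Feature profiles are drawn from a *probit copula*: a latent 10-vector
``z ~ N(0, R)`` is thresholded componentwise, ``presence_j = 1`` iff
``z_j < Phi^-1(p_j)``, which preserves the prescribed marginal prevalences
exactly in distribution while the latent correlation ``R`` induces tunable
dependence between features (the induced phi coefficient is a monotone, but
not identity, function of the latent correlation).

Dialogues are template exchanges flavored with scenario topics; for each
planted feature a deterministic injector rewrites or appends patient
utterances with that feature's canonical surface pattern. Injectors are
co-designed with the reference detector's rules (shared lexicons), which is
a detectability contract on synthetic data, not a claim about real speech.
Realism is an explicit non-goal.

Randomness is hierarchical: one integer seed drives independent
per-(subject, scenario) streams, so regenerating with a different
``n_subjects`` leaves earlier subjects' data unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .classify import classify_scenario
from .dialogue import DiarizedDialogue, SubjectRecord, TruthAnnotation, Utterance
from .errors import ConfigError
from .knowledge import (
    FEATURE_IDS,
    canonical_scenario,
    default_prevalence_table,
    included_scenarios,
)
from .lexicons import FLAT_TONE_MARKER, load_lexicon
from .profiles import FeatureProfile

__all__ = [
    "SyntheticCorpusConfig",
    "sample_profiles",
    "render_dialogue",
    "generate_corpus",
]

# --------------------------------------------------------------------------
# dialogue templates
#
# Base turns are deliberately bland and are kept disjoint from every
# detector lexicon and pattern, so an all-zero profile yields an all-zero
# detection (specificity contract). Examiner questions all have >= 5
# normalized tokens so a verbatim echo satisfies the F1 rule.

_SCENARIO_QUESTIONS: dict[str, list[str]] = {
    "S3": [
        "Can you describe what is happening in this picture?",
        "What else do you notice in the picture?",
        "Who do you think the people in the picture might be?",
    ],
    "S4": [
        "Can you tell me about your last holiday trip?",
        "What did you do after that happened?",
        "How did the rest of that day go?",
    ],
    "S5": [
        "Can you tell me about your current work or school?",
        "What does a normal day at work involve?",
        "How long have you been working or studying there?",
    ],
    "S6": [
        "Have you had any difficulties getting along with people?",
        "What kinds of things tend to annoy you?",
        "How do you usually handle a disagreement with someone?",
    ],
    "S7": [
        "What kinds of things make you feel happy?",
        "Can you tell me about a time you felt nervous?",
        "How do you usually show that you are pleased?",
    ],
    "S9": [
        "Can you explain what is going on in these cartoons?",
        "What happens next in the cartoon story?",
        "Why do you think the character did that?",
    ],
    "S11": [
        "Can you walk me through a normal day for you?",
        "How do you manage cooking and shopping for yourself?",
        "What do you usually do in the evenings at home?",
    ],
    "S12": [
        "Can you tell me a little about your friends?",
        "What do you and your friends do together?",
        "How did you first meet your closest friend?",
    ],
    "S13": [
        "Do you ever feel lonely during the week?",
        "What do you do when you are on your own?",
        "Who do you talk to when something bothers you?",
    ],
    "S14": [
        "What are your plans for the next few years?",
        "Where would you hope to be living in five years?",
        "What kind of job would you hope to have?",
    ],
    "S15": [
        "Can you make up a story using these objects?",
        "What happens to the hero of your story?",
        "How does your story come to an end?",
    ],
}

_GENERIC_QUESTIONS = [
    "Can you tell me a little more about that?",
    "How was that for you at the time?",
    "What usually happens on a typical day?",
    "Is there anything else about that you can share?",
]

_GENERIC_ANSWERS = [
    "It is mostly quiet from day to day.",
    "I spend the afternoons with my family.",
    "I go for a short walk most mornings.",
    "Work keeps me busy during the week.",
    "I read a little before going to bed.",
    "Not very often, maybe once a month.",
    "I am not sure, it depends on the day.",
    "That happened a long time ago.",
    "I usually take the bus into town.",
    "My brother visits on the weekend.",
    "I had cereal this morning before coming here.",
    "Sometimes, but it passes quickly.",
]

#: Fixed examiner coda lines. Innocuous as examiner speech (the detector
#: scans patient utterances only), but they carry a filler tag, a quoted
#: media line and a courtesy phrase, so a diarization role swap that
#: misattributes them to the patient produces spurious F6/F9/F7 hits --
#: the audited misdiagnosis mode.
BACKCHANNEL_PROMPT = "Anything else, or whatever comes to mind?"
MEDIA_PROBE_PROMPT = (
    'Some people repeat lines like "just keep swimming" from films - do you ever do that?'
)
CLOSING_PROMPT = "Okay, thank you for sharing all of that."
_CLOSING_REPLY = "No, that is all for today."
_PROBE_REPLY = "Not really, not that I remember."

_F3_TEMPLATES = [
    "He wants to answer that question himself.",
    "She needs a moment before the next question.",
    "You want to say it the right way.",
]

_F5_TEMPLATES = [
    "Henceforth I shall endeavor to recount the matter thusly.",
    "I do declare the day proceeded agreeably forthwith.",
    "Hitherto I have seen fit to comport myself quietly.",
]

_F6_TAGS = [", you know what I mean.", ", or whatever.", ", as they say."]


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Generator parameters.

    Parameters
    ----------
    n_subjects : int
        Number of simulated subjects.
    scenarios : sequence of str, optional
        Scenario tokens to generate; defaults to the 11 included scenarios.
    prevalence : DataFrame, optional
        Per-(scenario, feature) planting probabilities in [0, 1]; rows must
        cover every configured scenario, columns F1..F10. Defaults to the
        packaged per-scenario prevalence table.
    latent_correlation : ndarray, optional
        10x10 symmetric PSD matrix with unit diagonal governing feature
        co-occurrence. Defaults to the identity (independent features).
    dialogue_length : (int, int)
        Inclusive range of question-answer pair counts per dialogue; the
        lower bound must be >= 3 so replacement injectors never collide.
    seed : int
        Master seed of the hierarchical generator.
    """

    n_subjects: int
    scenarios: tuple[str, ...] = ()
    prevalence: pd.DataFrame = None
    latent_correlation: np.ndarray = None
    dialogue_length: tuple[int, int] = (4, 7)
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.n_subjects, int) or self.n_subjects < 1:
            raise ConfigError("n_subjects must be a positive integer")
        scenarios = tuple(self.scenarios) or tuple(included_scenarios())
        scenarios = tuple(canonical_scenario(s) for s in scenarios)
        object.__setattr__(self, "scenarios", scenarios)

        prev = self.prevalence if self.prevalence is not None else default_prevalence_table()
        prev = prev.copy()
        prev.index = [canonical_scenario(s) for s in prev.index]
        if list(prev.columns) != list(FEATURE_IDS):
            raise ConfigError(f"prevalence columns must be {list(FEATURE_IDS)}")
        missing = [s for s in scenarios if s not in prev.index]
        if missing:
            raise ConfigError(f"no prevalence row for scenario(s): {missing}")
        vals = prev.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any() or (vals > 1).any():
            raise ConfigError("prevalences must lie in [0, 1]")
        object.__setattr__(self, "prevalence", prev)

        corr = (
            np.asarray(self.latent_correlation, dtype=float)
            if self.latent_correlation is not None
            else np.eye(len(FEATURE_IDS))
        )
        k = len(FEATURE_IDS)
        if corr.shape != (k, k):
            raise ConfigError(f"latent_correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ConfigError("latent_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ConfigError("latent_correlation must have unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-9:
            raise ConfigError(
                f"latent_correlation must be positive semidefinite (min eigenvalue {eigvals.min():.3g})"
            )
        object.__setattr__(self, "latent_correlation", corr)

        lo, hi = self.dialogue_length
        if lo < 3 or hi < lo:
            raise ConfigError("dialogue_length must satisfy 3 <= lo <= hi")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")

    def correlation_factor(self) -> np.ndarray:
        """Square-root factor L of the latent correlation (z = L @ eps)."""
        w, v = np.linalg.eigh(self.latent_correlation)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _stream(seed: int, kind: int, subject_index: int, scenario: str) -> np.random.Generator:
    """Independent, stable RNG stream per (kind, subject, scenario)."""
    key = (kind, subject_index, int(scenario[1:]))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# --------------------------------------------------------------------------
# profile sampling


def sample_profiles(config: SyntheticCorpusConfig, scenario: str) -> list[FeatureProfile]:
    """Draw one feature profile per subject for one scenario.

    Thresholded latent multivariate normal: the marginal planting
    probability of feature j equals ``prevalence[scenario, j]`` exactly in
    distribution; ``Phi^-1(0)`` and ``Phi^-1(1)`` make features determinis-
    tically absent/present.
    """
    scenario = canonical_scenario(scenario)
    if scenario not in config.prevalence.index:
        raise ConfigError(f"no prevalence row for scenario {scenario}")
    p = config.prevalence.loc[scenario].to_numpy(dtype=float)
    thresholds = norm.ppf(p)  # -inf at p=0, +inf at p=1
    L = config.correlation_factor()
    profiles = []
    for i in range(config.n_subjects):
        rng = _stream(config.seed, 1, i, scenario)
        z = L @ rng.standard_normal(len(FEATURE_IDS))
        profiles.append(FeatureProfile(presence=tuple((z < thresholds).astype(int))))
    return profiles


# --------------------------------------------------------------------------
# dialogue rendering


class _Turn:
    """Mutable utterance under construction (identity-based equality)."""

    __slots__ = ("speaker", "text")

    def __init__(self, speaker: str, text: str):
        self.speaker = speaker
        self.text = text


def _sample(rng: np.random.Generator, pool: Sequence[str], k: int) -> list[str]:
    idx = rng.choice(len(pool), size=k, replace=k > len(pool))
    return [pool[int(i)] for i in np.atleast_1d(idx)]


def _choice(rng: np.random.Generator, pool: Sequence) -> object:
    return pool[int(rng.integers(len(pool)))]


def _strip_period(text: str) -> str:
    return text[:-1] if text.endswith(".") else text


def render_dialogue(
    profile: FeatureProfile,
    scenario: str,
    rng: np.random.Generator,
    subject_id: str = "subject",
    dialogue_length: tuple[int, int] = (4, 7),
) -> DiarizedDialogue:
    """Render one annotated examiner-patient exchange for a feature profile.

    For each feature with presence 1, one injector rewrites or appends
    patient utterances with that feature's canonical surface pattern; the
    truth annotation stores the profile, the rule-consistent scenario label
    and the planted utterance indices.
    """
    scenario = canonical_scenario(scenario)
    lo, hi = dialogue_length
    if lo < 3 or hi < lo:
        raise ConfigError("dialogue_length must satisfy 3 <= lo <= hi")
    k = int(rng.integers(lo, hi + 1))

    questions = _sample(rng, _SCENARIO_QUESTIONS.get(scenario, []) + _GENERIC_QUESTIONS, k)
    answers = _sample(rng, _GENERIC_ANSWERS, k)

    turns: list[_Turn] = []
    qa: list[tuple[_Turn, _Turn]] = []
    for q, a in zip(questions, answers):
        tq, ta = _Turn("examiner", q), _Turn("patient", a)
        turns.extend([tq, ta])
        qa.append((tq, ta))
    turns.append(_Turn("examiner", BACKCHANNEL_PROMPT))
    turns.append(_Turn("patient", _CLOSING_REPLY))
    turns.append(_Turn("examiner", MEDIA_PROBE_PROMPT))
    turns.append(_Turn("patient", _PROBE_REPLY))
    turns.append(_Turn("examiner", CLOSING_PROMPT))

    features = profile.to_features()
    planted: dict[str, list[_Turn]] = {}

    def _register(fid: str, turn: _Turn) -> None:
        planted.setdefault(fid, []).append(turn)

    def _insert_after(anchor: _Turn, new: _Turn) -> None:
        turns.insert(next(i for i, t in enumerate(turns) if t is anchor) + 1, new)

    base_answers = [ta for _, ta in qa]
    replace_pool = list(base_answers)
    append_pool = list(base_answers)

    # Reserve distinct targets for the two replacement injectors up front so
    # a later replacement never erases an earlier injection.
    reserved: dict[str, _Turn] = {}
    for fid in ("F5", "F10"):
        if fid in features:
            t = _choice(rng, replace_pool)
            replace_pool.remove(t)
            append_pool.remove(t)
            reserved[fid] = t

    def _pick_append() -> _Turn:
        if append_pool:
            t = _choice(rng, append_pool)
            append_pool.remove(t)
            return t
        candidates = [t for t in base_answers if t not in reserved.values()]
        return _choice(rng, candidates)

    if "F1" in features:
        tq, _ = qa[int(rng.integers(len(qa)))]
        echo = _Turn("patient", tq.text[0].lower() + tq.text[1:])
        _insert_after(tq, echo)
        _register("F1", echo)
    if "F2" in features:
        t = _pick_append()
        phrase = _choice(rng, load_lexicon("odd_content"))
        t.text = _strip_period(t.text) + f". I would describe it as {phrase}."
        _register("F2", t)
    if "F3" in features:
        new = _Turn("patient", str(_choice(rng, _F3_TEMPLATES)))
        _insert_after(_choice(rng, base_answers), new)
        _register("F3", new)
    if "F4" in features:
        t = _pick_append()
        t.text = _strip_period(t.text) + ". I was very sick then, ha ha, just kidding."
        _register("F4", t)
    if "F5" in features:
        t = reserved["F5"]
        t.text = str(_choice(rng, _F5_TEMPLATES))
        _register("F5", t)
    if "F6" in features:
        t = _pick_append()
        t.text = _strip_period(t.text) + str(_choice(rng, _F6_TAGS))
        _register("F6", t)
    if "F7" in features:
        new = _Turn("patient", "Oh, thank you, thank you very much.")
        _insert_after(_choice(rng, base_answers), new)
        _register("F7", new)
    if "F8" in features:
        phrase = str(_choice(rng, load_lexicon("social_phrases")))
        sentence = phrase[0].upper() + phrase[1:]
        new = _Turn("patient", f"{sentence}. {sentence}. {FLAT_TONE_MARKER}")
        _insert_after(_choice(rng, base_answers), new)
        _register("F8", new)
    if "F9" in features:
        quote = str(_choice(rng, load_lexicon("media_quotes")))
        new = _Turn("patient", f'They always said "{quote}" on the show.')
        _insert_after(_choice(rng, base_answers), new)
        _register("F9", new)
    if "F10" in features:
        t = reserved["F10"]
        phrase = _choice(rng, load_lexicon("cliches"))
        t.text = f"Well, {phrase}, that is how it goes."
        _register("F10", t)

    index_of = {id(t): i for i, t in enumerate(turns)}
    label, _rule = classify_scenario(features)
    truth = TruthAnnotation(
        profile=profile,
        label=label,
        planted={
            fid: tuple(sorted(index_of[id(t)] for t in ts)) for fid, ts in sorted(planted.items())
        },
    )
    return DiarizedDialogue(
        subject_id=subject_id,
        scenario_id=scenario,
        utterances=tuple(
            Utterance(index=i, speaker=t.speaker, text=t.text) for i, t in enumerate(turns)
        ),
        truth=truth,
    )


# --------------------------------------------------------------------------
# corpus generation


def generate_corpus(config: SyntheticCorpusConfig) -> list[SubjectRecord]:
    """Generate the full annotated corpus.

    One dialogue per configured scenario per subject. The subject-level
    truth label (stored as a binarized ``a4_score``) is 1 iff any scenario
    profile fires the A4 rules, so generator labels are rule-consistent by
    construction.
    """
    L = config.correlation_factor()
    thresholds = {
        s: norm.ppf(config.prevalence.loc[s].to_numpy(dtype=float)) for s in config.scenarios
    }
    records = []
    for i in range(config.n_subjects):
        subject_id = f"sub-{i + 1:03d}"
        dialogues = []
        any_positive = 0
        for scenario in config.scenarios:
            rng_p = _stream(config.seed, 1, i, scenario)
            z = L @ rng_p.standard_normal(len(FEATURE_IDS))
            profile = FeatureProfile(presence=tuple((z < thresholds[scenario]).astype(int)))
            rng_d = _stream(config.seed, 2, i, scenario)
            dlg = render_dialogue(
                profile, scenario, rng_d, subject_id=subject_id,
                dialogue_length=config.dialogue_length,
            )
            any_positive = max(any_positive, dlg.truth.label)
            dialogues.append(dlg)
        records.append(
            SubjectRecord(subject_id=subject_id, dialogues=tuple(dialogues), a4_score=any_positive)
        )
    return records
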