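"""Plain-text phrase lexicons shared by the synthetic injectors and the
deterministic reference detector.

Each lexicon is a packaged text file (one phrase per line, ``#`` comments
allowed) and is user-extensible: pass a custom phrase list to the detector or
generator to override the packaged default. Matching happens on a normalized
form of the text (lowercase, punctuation and apostrophes stripped, whitespace
collapsed), so ``"I'll be back."`` matches the lexicon entry ``i'll be back``.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

__all__ = [
    "LEXICON_NAMES",
    "FLAT_TONE_MARKER",
    "load_lexicon",
    "normalized_lexicon",
    "normalize_for_match",
    "tokens_for_match",
]

LEXICON_NAMES = (
    "odd_content",
    "archaic_formal",
    "fillers",
    "courtesy",
    "gratitude_cues",
    "social_phrases",
    "media_quotes",
    "cliches",
    "joke_markers",
    "serious_topics",
)

#: Synthetic marker standing in for monotone prosody (F8). Real transcripts
#: carry no textual trace of intonation; the marker keeps the feature
#: exercisable end-to-end on text alone.
FLAT_TONE_MARKER = "(in a flat tone)"

_APOSTROPHES = re.compile(r"[''`’‘]")
_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_for_match(text: str) -> str:
    """Lowercase, drop apostrophes, map punctuation to spaces, collapse runs."""
    t = _APOSTROPHES.sub("", text.lower())
    return _NON_ALNUM.sub(" ", t).strip()


def tokens_for_match(text: str) -> list[str]:
    n = normalize_for_match(text)
    return n.split() if n else []


@lru_cache(maxsize=None)
def load_lexicon(name: str) -> tuple[str, ...]:
    """Raw phrases of a packaged lexicon, in file order."""
    if name not in LEXICON_NAMES:
        raise KeyError(f"unknown lexicon {name!r}; available: {LEXICON_NAMES}")
    path = resources.files("sldscreen.data.lexicons").joinpath(f"{name}.txt")
    phrases = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            phrases.append(line)
    return tuple(phrases)


@lru_cache(maxsize=None)
def normalized_lexicon(name: str) -> tuple[str, ...]:
    """Match-normalized phrases of a packaged lexicon."""
    return tuple(normalize_for_match(p) for p in load_lexicon(name))


def contains_phrase(text_norm: str, phrases_norm: tuple[str, ...]) -> bool:
    """Whole-word containment of any normalized phrase in normalized text."""
    padded = f" {text_norm} "
    return any(f" {p} " in padded for p in phrases_norm)
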