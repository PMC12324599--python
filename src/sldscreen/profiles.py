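"""Binary feature profiles over the ten-feature taxonomy."""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import UnknownFeatureError
from .knowledge import FEATURE_IDS

__all__ = ["FeatureProfile", "validate_feature_ids"]


def validate_feature_ids(features: Iterable[str]) -> set[str]:
    """Validate and return a set of feature identifiers (subset of F1..F10)."""
    feats = set(features)
    unknown = feats - set(FEATURE_IDS)
    if unknown:
        raise UnknownFeatureError(f"unknown feature identifiers: {sorted(unknown)}")
    return feats


class FeatureProfile(BaseModel):
    """Ordered 10-vector of binary presence indicators, one per F1..F10.

    '1' marks the presence and '0' the absence of the corresponding
    linguistic-deficit feature in one scenario-level dialogue.
    """

    model_config = ConfigDict(frozen=True)

    presence: tuple[int, ...]

    @field_validator("presence")
    @classmethod
    def _check_presence(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        if len(v) != len(FEATURE_IDS):
            raise ValueError(f"presence vector must have length {len(FEATURE_IDS)}")
        if any(x not in (0, 1) for x in v):
            raise ValueError("presence entries must be 0 or 1")
        return tuple(int(x) for x in v)

    @classmethod
    def from_features(cls, features: Iterable[str]) -> "FeatureProfile":
        feats = validate_feature_ids(features)
        return cls(presence=tuple(int(f in feats) for f in FEATURE_IDS))

    @classmethod
    def zeros(cls) -> "FeatureProfile":
        return cls(presence=(0,) * len(FEATURE_IDS))

    def to_features(self) -> set[str]:
        return {f for f, p in zip(FEATURE_IDS, self.presence) if p}

    def as_array(self) -> np.ndarray:
        return np.asarray(self.presence, dtype=int)

    def __iter__(self) -> Iterator[int]:  # type: ignore[override]
        return iter(self.presence)

    def __getitem__(self, feature: str | int) -> int:
        if isinstance(feature, str):
            return self.presence[FEATURE_IDS.index(feature)]
        return self.presence[feature]
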