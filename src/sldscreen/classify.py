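"""Rule-based A4 classification and subject-level aggregation.

The scenario-level decision follows three printed rules over the detected
feature set:

(a) *critical rule* — if any critical feature is present (by default F1,
    echoic repetition, or F9, stereotyped media quoting), the dialogue is
    classified A4 > 0 (label 1);
(b) *cumulative rule* — if more than two other (non-critical) related
    features are present, the dialogue is classified A4 > 0 (label 1);
(c) otherwise the dialogue is classified A4 = 0 (label 0).

"More than two" is read as strictly greater than two (>= 3 non-critical
features); the threshold and the critical set are configuration knobs. At
the subject level a diagnosis is positive iff at least one scenario-level
decision is positive.

:class:`RuleBasedA4Classifier` wraps the rules as a scikit-learn classifier
over binary feature matrices so the stage composes with sklearn pipelines;
the module-level functions are thin wrappers operating on feature-ID sets.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import AggregationError
from .knowledge import DEFAULT_CRITICAL, FEATURE_IDS
from .profiles import validate_feature_ids

__all__ = [
    "ScenarioVerdict",
    "SubjectDiagnosis",
    "RuleBasedA4Classifier",
    "classify_scenario",
    "aggregate_subject",
    "classify_corpus",
    "DEFAULT_CUMULATIVE_THRESHOLD",
]

#: Strictly-greater cut for the cumulative rule: label 1 needs more than
#: this many non-critical features.
DEFAULT_CUMULATIVE_THRESHOLD = 2


class ScenarioVerdict(BaseModel):
    """Per-dialogue screening outcome."""

    model_config = ConfigDict(frozen=True)

    subject_id: str
    scenario_id: str
    sld_present: bool
    features: frozenset[str] = frozenset()
    raw_ref: Optional[tuple[str, str, str]] = None

    @field_validator("features")
    @classmethod
    def _known(cls, v: frozenset[str]) -> frozenset[str]:
        return frozenset(validate_feature_ids(v))


class SubjectDiagnosis(BaseModel):
    """Aggregated binary label for one subject, with rule provenance."""

    model_config = ConfigDict(frozen=True)

    subject_id: str
    label: int
    per_scenario: tuple[ScenarioVerdict, ...]
    rule_fired: dict[str, str]  # scenario_id -> critical | cumulative | none | affirmed

    @field_validator("label")
    @classmethod
    def _binary(cls, v: int) -> int:
        if v not in (0, 1):
            raise ValueError("label must be 0 or 1")
        return v


def classify_scenario(
    features: Iterable[str],
    critical_set: Iterable[str] | None = None,
    cumulative_threshold: int = DEFAULT_CUMULATIVE_THRESHOLD,
) -> tuple[int, str]:
    """Apply rules (a)-(c) to one detected feature set.

    Returns ``(label, rule)`` where ``rule`` names the first rule that fired:
    ``"critical"``, ``"cumulative"`` or ``"none"``.
    """
    feats = validate_feature_ids(features)
    critical = frozenset(validate_feature_ids(critical_set)) if critical_set is not None else DEFAULT_CRITICAL
    if feats & critical:
        return 1, "critical"
    if len(feats - critical) > cumulative_threshold:
        return 1, "cumulative"
    return 0, "none"


def aggregate_subject(verdicts: Sequence[ScenarioVerdict]) -> SubjectDiagnosis:
    """OR-aggregate scenario verdicts into one subject diagnosis.

    The diagnosis is positive iff at least one scenario verdict is positive.
    Scenario rule provenance is recomputed from the verdict's feature set;
    a positive verdict whose feature set alone would not fire any rule (the
    yes/no diagnosis route carries no features) is recorded as ``affirmed``.
    """
    verdicts = list(verdicts)
    if not verdicts:
        raise AggregationError("cannot aggregate an empty verdict list")
    subjects = {v.subject_id for v in verdicts}
    if len(subjects) != 1:
        raise AggregationError(f"verdicts mix subjects: {sorted(subjects)}")

    rule_fired: dict[str, str] = {}
    for v in verdicts:
        label, rule = classify_scenario(v.features)
        if bool(label) == v.sld_present:
            rule_fired[v.scenario_id] = rule
        else:
            rule_fired[v.scenario_id] = "affirmed" if v.sld_present else "none"

    label = int(any(v.sld_present for v in verdicts))
    return SubjectDiagnosis(
        subject_id=verdicts[0].subject_id,
        label=label,
        per_scenario=tuple(verdicts),
        rule_fired=rule_fired,
    )


def classify_corpus(
    verdicts: Iterable[ScenarioVerdict],
    critical_set: Iterable[str] | None = None,
    cumulative_threshold: int = DEFAULT_CUMULATIVE_THRESHOLD,
) -> list[SubjectDiagnosis]:
    """Re-classify every verdict's feature set, then aggregate per subject.

    ``sld_present`` of the incoming verdicts is recomputed from their feature
    sets under the configured rules, so the output is a pure function of the
    detected features. Deterministic: subjects keep first-appearance order.
    """
    grouped: dict[str, list[ScenarioVerdict]] = {}
    order: list[str] = []
    for v in verdicts:
        label, _ = classify_scenario(v.features, critical_set, cumulative_threshold)
        revised = v.model_copy(update={"sld_present": bool(label)})
        if v.subject_id not in grouped:
            grouped[v.subject_id] = []
            order.append(v.subject_id)
        grouped[v.subject_id].append(revised)
    return [aggregate_subject(grouped[s]) for s in order]


class RuleBasedA4Classifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn wrapper around the scenario-level A4 rules.

    Operates on an ``(n_samples, 10)`` binary matrix in F1..F10 column order
    (the output of :class:`~sldscreen.detector.FeatureRuleDetector`). The
    rules are fixed, so ``fit`` only records the class labels.

    Parameters
    ----------
    critical_features : tuple of str, default=("F1", "F9")
        Features that fire rule (a) on their own.
    cumulative_threshold : int, default=2
        Rule (b) fires when strictly more than this many non-critical
        features are present.
    """

    def __init__(
        self,
        critical_features: tuple[str, ...] = tuple(sorted(DEFAULT_CRITICAL)),
        cumulative_threshold: int = DEFAULT_CUMULATIVE_THRESHOLD,
    ):
        self.critical_features = critical_features
        self.cumulative_threshold = cumulative_threshold

    def _validate_matrix(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=int)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_IDS):
            raise ValueError(f"X must be (n_samples, {len(FEATURE_IDS)}) binary matrix")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("X entries must be 0 or 1")
        return X

    def fit(self, X, y=None) -> "RuleBasedA4Classifier":
        validate_feature_ids(self.critical_features)
        self._validate_matrix(X)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(FEATURE_IDS)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        X = self._validate_matrix(X)
        critical_mask = np.isin(FEATURE_IDS, tuple(self.critical_features))
        has_critical = X[:, critical_mask].any(axis=1)
        n_other = X[:, ~critical_mask].sum(axis=1)
        return (has_critical | (n_other > self.cumulative_threshold)).astype(int)

    def decision_rules(self, X) -> np.ndarray:
        """Name of the first rule fired per sample (critical/cumulative/none)."""
        check_is_fitted(self, "classes_")
        X = self._validate_matrix(X)
        critical_mask = np.isin(FEATURE_IDS, tuple(self.critical_features))
        has_critical = X[:, critical_mask].any(axis=1)
        n_other = X[:, ~critical_mask].sum(axis=1)
        out = np.full(X.shape[0], "none", dtype=object)
        out[n_other > self.cumulative_threshold] = "cumulative"
        out[has_critical] = "critical"
        return out
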