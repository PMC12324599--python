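"""Feature-level analytics: binary correlations, prevalence, detection counts.

All statistics operate on 0/1 presence indicators. The pairwise Pearson
coefficient on binary indicators is algebraically the phi coefficient of the
2x2 contingency table; pairs involving a zero-variance feature are reported
as *undefined* (NaN plus a mask), never coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ScenarioVerdict
from .dialogue import SubjectRecord
from .errors import AlignmentError, InsufficientDataError
from .knowledge import FEATURE_IDS
from .profiles import FeatureProfile

__all__ = [
    "CorrelationMatrix",
    "PrevalenceTable",
    "feature_correlations",
    "prevalence_by_scenario",
    "detection_counts",
    "scenario_profile_pairs",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """10x10 pairwise Pearson (phi) coefficients over binary indicators."""

    values: pd.DataFrame
    n: int
    undefined_mask: pd.DataFrame

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        defined = ~self.undefined_mask.to_numpy(dtype=bool)
        if not np.allclose(np.where(defined, v, 0.0), np.where(defined, v, 0.0).T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")


@dataclass(frozen=True)
class PrevalenceTable:
    """Per-(scenario, feature) presence fractions with per-scenario counts."""

    values: pd.DataFrame
    n: pd.Series
    undefined_mask: pd.DataFrame


def _profile_matrix(profiles: Iterable) -> np.ndarray:
    rows = []
    for p in profiles:
        if isinstance(p, FeatureProfile):
            rows.append(p.as_array())
        else:
            rows.append(np.asarray(p, dtype=int))
    X = np.asarray(rows, dtype=int)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_IDS):
        raise ValueError(f"profiles must be (n, {len(FEATURE_IDS)}) binary")
    return X


def feature_correlations(
    profiles: Iterable,
    scope: str = "all",
    scenarios: Sequence[str] | None = None,
) -> "CorrelationMatrix | dict[str, CorrelationMatrix]":
    """Pairwise Pearson coefficients between the ten binary features.

    Parameters
    ----------
    profiles
        Feature profiles (or raw 0/1 rows), one per scenario-level sample.
    scope
        ``"all"`` pools every sample into one matrix; ``"per-scenario"``
        returns one matrix per scenario and requires ``scenarios`` (one
        token per profile).

    Zero-variance features make every pair involving them undefined (NaN and
    ``undefined_mask``); defined diagonal entries are exactly 1.
    """
    X = _profile_matrix(profiles)
    if scope == "per-scenario":
        if scenarios is None or len(scenarios) != X.shape[0]:
            raise ValueError("per-scenario scope needs one scenario token per profile")
        out: dict[str, CorrelationMatrix] = {}
        for s in dict.fromkeys(scenarios):
            sel = [i for i, t in enumerate(scenarios) if t == s]
            out[s] = feature_correlations(X[sel])
        return out
    if scope != "all":
        raise ValueError(f"unknown scope {scope!r}")

    n = X.shape[0]
    if n < 2:
        raise InsufficientDataError("need at least 2 profiles for correlations")

    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc
    sd = np.sqrt(np.diag(cov))
    defined = sd > 0
    denom = np.outer(sd, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / denom
    undefined = ~np.outer(defined, defined)
    r[undefined] = np.nan
    # clamp tiny floating excursions outside [-1, 1]
    r[~undefined] = np.clip(r[~undefined], -1.0, 1.0)
    idx = list(FEATURE_IDS)
    return CorrelationMatrix(
        values=pd.DataFrame(r, index=idx, columns=idx),
        n=n,
        undefined_mask=pd.DataFrame(undefined, index=idx, columns=idx),
    )


def scenario_profile_pairs(data: Iterable) -> list[tuple[str, np.ndarray]]:
    """Extract (scenario_id, presence-vector) pairs from mixed inputs.

    Accepts subject records carrying truth annotations, scenario verdicts,
    or explicit ``(scenario_id, profile)`` pairs.
    """
    pairs: list[tuple[str, np.ndarray]] = []
    for item in data:
        if isinstance(item, SubjectRecord):
            for d in item.dialogues:
                if d.truth is not None:
                    pairs.append((d.scenario_id, d.truth.profile.as_array()))
        elif isinstance(item, ScenarioVerdict):
            pairs.append((item.scenario_id, FeatureProfile.from_features(item.features).as_array()))
        else:
            scenario, profile = item
            if isinstance(profile, FeatureProfile):
                profile = profile.as_array()
            pairs.append((scenario, np.asarray(profile, dtype=int)))
    return pairs


def prevalence_by_scenario(
    data: Iterable, scenarios: Sequence[str] | None = None
) -> PrevalenceTable:
    """Fraction of samples in each scenario exhibiting each feature.

    ``entry(s, f) = (# samples in s with feature f) / (# samples in s)``.
    Scenarios requested via ``scenarios`` but observed in zero samples get
    undefined (NaN, masked) rows rather than zeros.
    """
    pairs = scenario_profile_pairs(data)
    by_scenario: dict[str, list[np.ndarray]] = {}
    for s, vec in pairs:
        by_scenario.setdefault(s, []).append(vec)

    row_order = list(scenarios) if scenarios is not None else sorted(
        by_scenario, key=lambda s: int(s[1:])
    )
    values = np.full((len(row_order), len(FEATURE_IDS)), np.nan)
    counts = np.zeros(len(row_order), dtype=int)
    for i, s in enumerate(row_order):
        vecs = by_scenario.get(s, [])
        counts[i] = len(vecs)
        if vecs:
            values[i] = np.mean(vecs, axis=0)
    undefined = np.isnan(values)
    cols = list(FEATURE_IDS)
    return PrevalenceTable(
        values=pd.DataFrame(values, index=row_order, columns=cols),
        n=pd.Series(counts, index=row_order, name="n"),
        undefined_mask=pd.DataFrame(undefined, index=row_order, columns=cols),
    )


def _verdict_feature_map(run: Iterable) -> dict[tuple[str, str], frozenset[str]]:
    out: dict[tuple[str, str], frozenset[str]] = {}
    for item in run:
        if isinstance(item, ScenarioVerdict):
            out[(item.subject_id, item.scenario_id)] = frozenset(item.features)
        else:
            key, feats = item
            out[tuple(key)] = frozenset(feats)
    return out


def detection_counts(run_a: Iterable, run_b: Iterable) -> pd.DataFrame:
    """Per-feature detection totals of two runs over the same dialogues.

    Accepts scenario verdicts or ``((subject, scenario), feature-set)``
    pairs. The runs must cover exactly the same dialogues; the result has
    one row per feature with both totals and their difference (a - b).
    """
    a = _verdict_feature_map(run_a)
    b = _verdict_feature_map(run_b)
    if a.keys() != b.keys():
        only_a = sorted(a.keys() - b.keys())[:3]
        only_b = sorted(b.keys() - a.keys())[:3]
        raise AlignmentError(
            f"runs cover different dialogues (e.g. only in a: {only_a}, only in b: {only_b})"
        )
    rows = []
    for fid in FEATURE_IDS:
        ca = sum(fid in feats for feats in a.values())
        cb = sum(fid in feats for feats in b.values())
        rows.append({"feature": fid, "run_a": ca, "run_b": cb, "difference": ca - cb})
    return pd.DataFrame(rows).set_index("feature")


def plot_correlation_heatmap(matrix: CorrelationMatrix, path: str) -> None:
    """Render a correlation matrix as a heatmap image (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(FEATURE_IDS)), FEATURE_IDS, rotation=45)
    ax.set_yticks(range(len(FEATURE_IDS)), FEATURE_IDS)
    fig.colorbar(im, ax=ax, label="Pearson r (phi)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
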