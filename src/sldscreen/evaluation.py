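"""Metrics, the five-subset leave-one-subset-out harness, and the
diarization-perturbation audit.

Metrics follow the standard confusion-matrix definitions (accuracy, positive
predictive value, sensitivity, F1 as the harmonic mean of PPV and
sensitivity). Pooled evaluation combines predictions from all folds into a
single vector before computing metrics (not a macro average over folds).
Zero-denominator ratios are reported as undefined with a warning rather than
silently coerced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import classify_corpus
from .dialogue import DiarizedDialogue, SubjectRecord, Utterance
from .errors import AlignmentError, CoverageError, FoldError
from .knowledge import a4_to_label
from .parsing import verdict_from_response
from .prompts import build_feature_prompt

__all__ = [
    "MetricsReport",
    "FoldPlan",
    "compute_metrics",
    "f1_from",
    "make_folds",
    "pooled_evaluation",
    "perturb_roles",
    "diarization_sweep",
]


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts plus derived fractions; None marks undefined ratios."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float | None
    ppv: float | None
    sensitivity: float | None
    f1: float | None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "undefined": list(self.undefined),
        }


def f1_from(ppv: float | None, sensitivity: float | None) -> float | None:
    """Harmonic mean of PPV and sensitivity; None if undefined."""
    if ppv is None or sensitivity is None:
        return None
    if ppv + sensitivity == 0:
        return None
    return 2 * ppv * sensitivity / (ppv + sensitivity)


def compute_metrics(predicted: Sequence[int], truth: Sequence[int]) -> MetricsReport:
    """Confusion counts and the four screening metrics for binary labels."""
    pred = np.asarray(predicted, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.shape != true.shape or pred.ndim != 1:
        raise AlignmentError(
            f"predicted and truth must be equal-length 1-D vectors, got {pred.shape} vs {true.shape}"
        )
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("labels must be 0 or 1")

    tp = int(((pred == 1) & (true == 1)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())

    undefined: list[str] = []
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else None
    if total == 0:
        undefined.append("accuracy")
    ppv = tp / (tp + fp) if (tp + fp) else None
    if tp + fp == 0:
        undefined.append("ppv")
    sensitivity = tp / (tp + fn) if (tp + fn) else None
    if tp + fn == 0:
        undefined.append("sensitivity")
    f1 = f1_from(ppv, sensitivity)
    if f1 is None:
        undefined.append("f1")
    if undefined:
        warnings.warn(f"undefined metrics (zero denominator): {undefined}", stacklevel=2)
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=accuracy, ppv=ppv, sensitivity=sensitivity, f1=f1,
        undefined=tuple(undefined),
    )


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of samples to k test folds (each used exactly once)."""

    assignments: dict[Hashable, int]
    k: int
    grouping: str
    order: tuple = ()

    def fold_of(self, sample: Hashable) -> int:
        return self.assignments[sample]

    def test_samples(self, fold: int) -> list:
        return [s for s in self.order if self.assignments[s] == fold]


def _default_subject_of(sample: Hashable) -> Hashable:
    return sample[0] if isinstance(sample, tuple) else sample


def make_folds(
    samples: Sequence[Hashable],
    k: int = 5,
    seed: int = 0,
    grouping: str = "subject",
    subject_of=None,
) -> FoldPlan:
    """Seeded shuffle + round-robin assignment into k near-equal folds.

    ``grouping="subject"`` keeps all of a subject's samples in one fold
    (subjects are the shuffled units; prevents leakage when a subject
    contributes several scenario-level samples). ``grouping="sample"``
    shuffles the samples themselves, giving fold sizes that differ by at
    most one.
    """
    samples = list(samples)
    if len(set(samples)) != len(samples):
        raise FoldError("samples must be unique")
    rng = np.random.default_rng(seed)

    if grouping == "sample":
        units: list = list(samples)
    elif grouping == "subject":
        subject_of = subject_of or _default_subject_of
        units = list(dict.fromkeys(subject_of(s) for s in samples))
    else:
        raise FoldError(f"unknown grouping {grouping!r}")
    if len(units) < k:
        raise FoldError(f"{len(units)} unit(s) cannot fill {k} folds")

    perm = [units[int(i)] for i in rng.permutation(len(units))]
    unit_fold = {u: (i % k) + 1 for i, u in enumerate(perm)}

    if grouping == "sample":
        assignments = {s: unit_fold[s] for s in samples}
    else:
        assignments = {s: unit_fold[subject_of(s)] for s in samples}
    return FoldPlan(assignments=assignments, k=k, grouping=grouping, order=tuple(samples))


def pooled_evaluation(
    plan: FoldPlan,
    fold_predictions: Mapping[int, Mapping[Hashable, int]],
    truth: Mapping[Hashable, int],
) -> MetricsReport:
    """Combine per-fold test predictions into one pooled metric report.

    Every sample of the plan must be predicted exactly once, by the fold it
    is assigned to; gaps, overlaps or stray samples raise a coverage error.
    """
    seen: dict[Hashable, int] = {}
    for fold, preds in fold_predictions.items():
        for sample, label in preds.items():
            if sample not in plan.assignments:
                raise CoverageError(f"prediction for unknown sample {sample!r}")
            if plan.assignments[sample] != fold:
                raise CoverageError(
                    f"sample {sample!r} predicted in fold {fold} but assigned to "
                    f"fold {plan.assignments[sample]}"
                )
            if sample in seen:
                raise CoverageError(f"sample {sample!r} predicted more than once")
            seen[sample] = int(label)
    missing = [s for s in plan.order if s not in seen]
    if missing:
        raise CoverageError(f"{len(missing)} sample(s) never predicted, e.g. {missing[:3]}")
    pred = [seen[s] for s in plan.order]
    true = [int(truth[s]) for s in plan.order]
    return compute_metrics(pred, true)


def perturb_roles(
    dialogue: DiarizedDialogue,
    swap_fraction: float,
    rng: np.random.Generator,
    merge: bool = False,
) -> DiarizedDialogue:
    """Simulate diarization errors by flipping speaker roles.

    Reassigns the role of ``round(swap_fraction * n)`` seeded-random
    utterances. With ``merge=True``, runs of consecutive same-role
    utterances that contain a swapped turn are additionally merged into one
    utterance (mimicking misattributed speech being absorbed into the
    neighbouring turn). Truth annotations are left untouched.
    """
    if not 0.0 <= swap_fraction <= 1.0:
        raise ValueError("swap_fraction must lie in [0, 1]")
    n = len(dialogue.utterances)
    m = int(round(swap_fraction * n))
    if m == 0:
        return dialogue
    swapped = set(int(i) for i in rng.choice(n, size=m, replace=False))
    flip = {"examiner": "patient", "patient": "examiner"}
    turns = [
        (flip[u.speaker] if i in swapped else u.speaker, u.text, i in swapped)
        for i, u in enumerate(dialogue.utterances)
    ]

    if merge:
        merged: list[list] = []
        for speaker, text, was_swapped in turns:
            if merged and merged[-1][0] == speaker and (was_swapped or merged[-1][2]):
                merged[-1][1] += " " + text
                merged[-1][2] = merged[-1][2] or was_swapped
            else:
                merged.append([speaker, text, was_swapped])
        turns = [(s, t, w) for s, t, w in merged]

    return DiarizedDialogue(
        subject_id=dialogue.subject_id,
        scenario_id=dialogue.scenario_id,
        utterances=tuple(
            Utterance(index=i, speaker=s, text=t) for i, (s, t, _) in enumerate(turns)
        ),
        truth=dialogue.truth,
    )


def subject_truth_labels(records: Iterable[SubjectRecord]) -> dict[str, int]:
    """Binary ground-truth label per subject (binarized A4, or OR of truth)."""
    out: dict[str, int] = {}
    for rec in records:
        if rec.a4_score is not None:
            out[rec.subject_id] = a4_to_label(rec.a4_score)
        else:
            labels = [d.truth.label for d in rec.dialogues if d.truth is not None]
            if not labels:
                raise AlignmentError(f"subject {rec.subject_id!r} has no ground truth")
            out[rec.subject_id] = int(any(labels))
    return out


def diarization_sweep(
    records: Sequence[SubjectRecord],
    swap_fractions: Sequence[float],
    seeds: Sequence[int],
    backend=None,
    merge: bool = False,
) -> pd.DataFrame:
    """Audit the full pipeline under increasing role-swap corruption.

    For every (swap fraction, seed) pair, each dialogue's speaker roles are
    perturbed, the full prompt -> detector -> parser -> rule-classifier
    pipeline is re-run, and subject-level false positives against the clean
    ground truth are counted. Returns one row per (fraction, seed).
    """
    from .detector import ReferenceBackend, detect  # local import to avoid cycle

    backend = backend or ReferenceBackend()
    truth = subject_truth_labels(records)
    rows = []
    for frac in swap_fractions:
        for seed in seeds:
            rng = np.random.default_rng(seed)
            verdicts = []
            for rec in records:
                for dlg in rec.dialogues:
                    noisy = perturb_roles(dlg, frac, rng, merge=merge)
                    prompt = build_feature_prompt(noisy)
                    verdicts.append(verdict_from_response(detect(prompt, backend)))
            diagnoses = classify_corpus(verdicts)
            fp = sum(1 for d in diagnoses if d.label == 1 and truth[d.subject_id] == 0)
            fn = sum(1 for d in diagnoses if d.label == 0 and truth[d.subject_id] == 1)
            n_neg = sum(1 for v in truth.values() if v == 0)
            rows.append(
                {
                    "swap_fraction": frac,
                    "seed": seed,
                    "false_positives": fp,
                    "false_negatives": fn,
                    "n_negative_subjects": n_neg,
                    "fp_rate": fp / n_neg if n_neg else np.nan,
                }
            )
    return pd.DataFrame(rows)
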