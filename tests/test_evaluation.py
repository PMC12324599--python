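"""Metrics, fold plans, pooled evaluation, and the diarization audit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sldscreen import (
    FeatureProfile,
    SyntheticCorpusConfig,
    compute_metrics,
    diarization_sweep,
    f1_from,
    generate_corpus,
    make_folds,
    perturb_roles,
    pooled_evaluation,
)
from sldscreen.errors import AlignmentError, CoverageError, FoldError
from sldscreen.simulate import render_dialogue


def _labels(tp, fp, fn, tn):
    pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
    true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
    return pred, true


class TestComputeMetrics:
    def test_worked_confusion_example(self):
        report = compute_metrics(*_labels(3, 1, 1, 5))
        assert (report.tp, report.fp, report.fn, report.tn) == (3, 1, 1, 5)
        assert report.accuracy == pytest.approx(0.8)
        assert report.ppv == pytest.approx(0.75)
        assert report.sensitivity == pytest.approx(0.75)
        assert report.f1 == pytest.approx(0.75)

    def test_perfect_predictions(self):
        report = compute_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert report.accuracy == report.ppv == report.sensitivity == report.f1 == 1.0
        assert report.undefined == ()

    def test_zero_denominators_flagged_not_coerced(self):
        with pytest.warns(UserWarning, match="undefined"):
            report = compute_metrics([0, 0, 0], [1, 0, 1])
        assert report.ppv is None and report.f1 is None
        assert "ppv" in report.undefined and "f1" in report.undefined
        assert report.sensitivity == 0.0

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            compute_metrics([1, 0], [1])

    def test_f1_harmonic_mean_from_printed_cells(self):
        # published PPV/sensitivity pairs reproduce their printed F1 cells;
        # the third pair lands one unit of the last printed place away
        # because its inputs are themselves two-decimal roundings
        assert round(100 * f1_from(0.7152, 0.9322), 2) == 80.94
        assert round(100 * f1_from(0.7076, 0.9051), 2) == 79.43
        assert round(100 * f1_from(0.9106, 0.8249), 2) == 86.56

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        fn=st.integers(0, 30), tn=st.integers(0, 30),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_f1_equivalence_and_bounds(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # undefined-metric warnings are expected here
            report = compute_metrics(*_labels(tp, fp, fn, tn))
        if report.f1 is not None:
            # algebraic identity: F1 = 2TP / (2TP + FP + FN)
            assert report.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))
            assert min(report.ppv, report.sensitivity) - 1e-12 <= report.f1
            assert report.f1 <= max(report.ppv, report.sensitivity) + 1e-12


class TestMakeFolds:
    def test_equal_split(self):
        plan = make_folds(list(range(10)), k=5, seed=0, grouping="sample")
        sizes = sorted(
            sum(1 for f in plan.assignments.values() if f == fold) for fold in range(1, 6)
        )
        assert sizes == [2, 2, 2, 2, 2]

    def test_463_samples_split_93_93_93_92_92(self):
        plan = make_folds(list(range(463)), k=5, seed=1, grouping="sample")
        sizes = sorted(
            (sum(1 for f in plan.assignments.values() if f == fold) for fold in range(1, 6)),
            reverse=True,
        )
        assert sizes == [93, 93, 93, 92, 92]

    def test_deterministic_under_seed(self):
        samples = [(f"s{i}", f"S{3 + i % 5}") for i in range(30)]
        assert make_folds(samples, seed=7) == make_folds(samples, seed=7)
        assert make_folds(samples, seed=7) != make_folds(samples, seed=8)

    def test_subject_grouping_never_splits_a_subject(self):
        samples = [(f"s{i}", f"S{k}") for i in range(12) for k in (3, 4, 5)]
        plan = make_folds(samples, k=5, seed=3, grouping="subject")
        by_subject = {}
        for (subj, _), fold in plan.assignments.items():
            by_subject.setdefault(subj, set()).add(fold)
        assert all(len(folds) == 1 for folds in by_subject.values())

    def test_every_sample_in_exactly_one_fold(self):
        samples = list(range(23))
        plan = make_folds(samples, k=5, seed=0, grouping="sample")
        assert sorted(plan.assignments) == samples
        assert set(plan.assignments.values()) == {1, 2, 3, 4, 5}

    def test_too_few_units(self):
        with pytest.raises(FoldError):
            make_folds([("a", "S3"), ("a", "S4")], k=5, grouping="subject")
        with pytest.raises(FoldError):
            make_folds([1, 2, 3], k=5, grouping="sample")


class TestPooledEvaluation:
    @staticmethod
    def _setup(n=20):
        samples = list(range(n))
        plan = make_folds(samples, k=5, seed=0, grouping="sample")
        truth = {s: s % 2 for s in samples}
        preds = {
            fold: {s: truth[s] for s in plan.test_samples(fold)} for fold in range(1, 6)
        }
        return plan, preds, truth

    def test_perfect_pooling(self):
        plan, preds, truth = self._setup()
        report = pooled_evaluation(plan, preds, truth)
        assert report.accuracy == 1.0

    def test_fold_order_invariance(self):
        plan, preds, truth = self._setup()
        reordered = dict(reversed(list(preds.items())))
        assert pooled_evaluation(plan, preds, truth) == pooled_evaluation(plan, reordered, truth)

    def test_missing_sample_rejected(self):
        plan, preds, truth = self._setup()
        del preds[1][plan.test_samples(1)[0]]
        with pytest.raises(CoverageError, match="never predicted"):
            pooled_evaluation(plan, preds, truth)

    def test_wrong_fold_rejected(self):
        plan, preds, truth = self._setup()
        stray = plan.test_samples(1)[0]
        preds[2][stray] = truth[stray]
        with pytest.raises(CoverageError):
            pooled_evaluation(plan, preds, truth)

    def test_unknown_sample_rejected(self):
        plan, preds, truth = self._setup()
        preds[1][999] = 1
        with pytest.raises(CoverageError, match="unknown sample"):
            pooled_evaluation(plan, preds, truth)


class TestPerturbRoles:
    def test_zero_fraction_is_identity(self, rng):
        d = render_dialogue(FeatureProfile.from_features({"F2"}), "S3", rng)
        assert perturb_roles(d, 0.0, np.random.default_rng(0)) == d

    def test_full_swap_flips_every_role(self, rng):
        d = render_dialogue(FeatureProfile.zeros(), "S3", rng)
        flipped = perturb_roles(d, 1.0, np.random.default_rng(0))
        assert all(
            a.speaker != b.speaker for a, b in zip(d.utterances, flipped.utterances)
        )

    def test_truth_annotation_untouched(self, rng):
        d = render_dialogue(FeatureProfile.from_features({"F1", "F6"}), "S4", rng)
        assert perturb_roles(d, 0.7, np.random.default_rng(3)).truth == d.truth

    def test_swap_count(self, rng):
        d = render_dialogue(FeatureProfile.zeros(), "S5", rng)
        n = len(d.utterances)
        noisy = perturb_roles(d, 0.5, np.random.default_rng(1))
        flips = sum(a.speaker != b.speaker for a, b in zip(d.utterances, noisy.utterances))
        assert flips == round(0.5 * n)

    def test_invalid_fraction(self, rng):
        d = render_dialogue(FeatureProfile.zeros(), "S5", rng)
        with pytest.raises(ValueError):
            perturb_roles(d, 1.5, np.random.default_rng(0))

    def test_merge_mode_absorbs_swapped_turns(self, rng):
        d = render_dialogue(FeatureProfile.zeros(), "S5", rng)
        merged = perturb_roles(d, 0.5, np.random.default_rng(2), merge=True)
        assert len(merged.utterances) <= len(d.utterances)
        assert [u.index for u in merged.utterances] == list(range(len(merged.utterances)))


class TestDiarizationSweep:
    def test_false_positives_grow_with_swap_fraction(self, negative_corpus):
        df = diarization_sweep(negative_corpus, [0.0, 0.5, 1.0], seeds=[0, 1, 2])
        means = df.groupby("swap_fraction")["false_positives"].mean()
        assert means.loc[0.0] == 0
        assert means.loc[0.5] > 0
        assert means.loc[0.0] <= means.loc[0.5] <= means.loc[1.0]
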