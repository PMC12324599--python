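"""Synthetic corpus generator: copula marginals, injectors, determinism."""

import numpy as np
import pytest

from sldscreen import (
    FEATURE_IDS,
    FeatureProfile,
    SyntheticCorpusConfig,
    classify_scenario,
    default_prevalence_table,
    generate_corpus,
    included_scenarios,
    reference_feature_rules,
    sample_profiles,
    write_corpus,
)
from sldscreen.errors import ConfigError
from sldscreen.simulate import render_dialogue


def _profile_matrix(profiles):
    return np.array([p.as_array() for p in profiles])


class TestConfigValidation:
    def test_defaults(self):
        cfg = SyntheticCorpusConfig(n_subjects=3)
        assert cfg.scenarios == tuple(included_scenarios())
        assert cfg.prevalence.equals(default_prevalence_table())
        assert np.array_equal(cfg.latent_correlation, np.eye(10))

    @pytest.mark.parametrize("n", [0, -2, 1.5])
    def test_bad_n_subjects(self, n):
        with pytest.raises(ConfigError):
            SyntheticCorpusConfig(n_subjects=n)

    def test_prevalence_out_of_range(self):
        prev = default_prevalence_table()
        prev.loc["S3", "F1"] = 1.2
        with pytest.raises(ConfigError, match="\\[0, 1\\]"):
            SyntheticCorpusConfig(n_subjects=2, prevalence=prev)

    def test_excluded_scenario_needs_user_prevalence(self):
        with pytest.raises(ConfigError, match="S1"):
            SyntheticCorpusConfig(n_subjects=2, scenarios=("S1",))

    def test_asymmetric_correlation_rejected(self):
        corr = np.eye(10)
        corr[0, 1] = 0.5
        with pytest.raises(ConfigError, match="symmetric"):
            SyntheticCorpusConfig(n_subjects=2, latent_correlation=corr)

    def test_non_psd_correlation_rejected(self):
        corr = np.eye(10)
        corr[0, 1] = corr[1, 0] = 0.9
        corr[0, 2] = corr[2, 0] = 0.9
        corr[1, 2] = corr[2, 1] = -0.9
        with pytest.raises(ConfigError, match="semidefinite"):
            SyntheticCorpusConfig(n_subjects=2, latent_correlation=corr)

    def test_dialogue_length_lower_bound(self):
        with pytest.raises(ConfigError):
            SyntheticCorpusConfig(n_subjects=2, dialogue_length=(2, 5))


class TestProfileSampling:
    def test_zero_prevalence_gives_all_zero(self, zero_prevalence):
        cfg = SyntheticCorpusConfig(n_subjects=50, prevalence=zero_prevalence, seed=3)
        assert not _profile_matrix(sample_profiles(cfg, "S3")).any()

    def test_unit_prevalence_gives_all_one(self):
        prev = default_prevalence_table()
        prev.loc[:, :] = 1.0
        cfg = SyntheticCorpusConfig(n_subjects=50, prevalence=prev, seed=3)
        assert _profile_matrix(sample_profiles(cfg, "S3")).all()

    def test_marginals_recovered_within_three_se(self):
        cfg = SyntheticCorpusConfig(n_subjects=800, seed=21)
        X = _profile_matrix(sample_profiles(cfg, "S5"))
        p = default_prevalence_table().loc["S5"].to_numpy()
        se = np.sqrt(p * (1 - p) / len(X))
        assert (np.abs(X.mean(axis=0) - p) <= 3 * se + 1e-12).all()

    def test_latent_correlation_raises_cooccurrence(self):
        prev = default_prevalence_table()
        prev.loc[:, :] = 0.5
        corr = np.eye(10)
        corr[0, 1] = corr[1, 0] = 0.8
        dep = SyntheticCorpusConfig(n_subjects=3000, prevalence=prev, latent_correlation=corr, seed=9)
        ind = SyntheticCorpusConfig(n_subjects=3000, prevalence=prev, seed=9)
        phi_dep = np.corrcoef(_profile_matrix(sample_profiles(dep, "S3"))[:, :2].T)[0, 1]
        phi_ind = np.corrcoef(_profile_matrix(sample_profiles(ind, "S3"))[:, :2].T)[0, 1]
        # the induced phi is monotone in the latent rho but attenuated below it
        assert phi_dep - phi_ind > 0.2
        assert phi_dep < 0.8

    def test_unknown_scenario_rejected(self):
        cfg = SyntheticCorpusConfig(n_subjects=2)
        with pytest.raises(ConfigError):
            sample_profiles(cfg, "S1")


class TestRenderDialogue:
    def test_echo_injection_matches_previous_examiner_turn(self, rng):
        d = render_dialogue(FeatureProfile.from_features({"F1"}), "S3", rng)
        (echo_idx,) = d.truth.planted["F1"]
        echo = d.utterances[echo_idx]
        previous = d.utterances[echo_idx - 1]
        assert echo.speaker == "patient" and previous.speaker == "examiner"
        assert echo.text.lower().rstrip("?.") == previous.text.lower().rstrip("?.")

    def test_all_zero_profile_triggers_nothing(self, rng):
        d = render_dialogue(FeatureProfile.zeros(), "S7", rng)
        assert reference_feature_rules(d).to_features() == set()
        assert d.truth.planted == {}

    @pytest.mark.parametrize("fid", FEATURE_IDS)
    def test_each_injector_is_detected(self, fid, rng):
        d = render_dialogue(FeatureProfile.from_features({fid}), "S11", rng)
        assert reference_feature_rules(d).to_features() == {fid}

    def test_planted_indices_point_at_patient_utterances(self, rng):
        d = render_dialogue(FeatureProfile.from_features({"F6", "F9"}), "S12", rng)
        for fid, indices in d.truth.planted.items():
            for i in indices:
                assert d.utterances[i].speaker == "patient"

    def test_truth_label_is_rule_consistent(self, rng):
        for feats in ({"F1"}, {"F2", "F3"}, {"F2", "F3", "F5", "F6"}, set()):
            d = render_dialogue(FeatureProfile.from_features(feats), "S4", rng)
            assert d.truth.label == classify_scenario(feats)[0]


class TestGenerateCorpus:
    def test_shape_and_annotation(self):
        records = generate_corpus(SyntheticCorpusConfig(n_subjects=5, seed=2))
        assert len(records) == 5
        for rec in records:
            assert len(rec.dialogues) == 11
            assert all(d.truth is not None for d in rec.dialogues)

    def test_zero_prevalence_labels_all_negative(self, negative_corpus):
        assert all(rec.a4_score == 0 for rec in negative_corpus)

    def test_forced_critical_feature_labels_all_positive(self, zero_prevalence):
        prev = zero_prevalence.copy()
        prev.loc["S3", "F1"] = 1.0
        records = generate_corpus(
            SyntheticCorpusConfig(n_subjects=6, seed=4, prevalence=prev, scenarios=("S3", "S4"))
        )
        # independent check: the rule classifier fires rule (a) on every truth profile
        for rec in records:
            s3 = next(d for d in rec.dialogues if d.scenario_id == "S3")
            assert classify_scenario(s3.truth.profile.to_features()) == (1, "critical")
            assert rec.a4_score == 1

    def test_byte_identical_under_same_seed(self, tmp_path):
        cfg = SyntheticCorpusConfig(n_subjects=4, seed=13)
        for name in ("a", "b"):
            write_corpus(generate_corpus(cfg), tmp_path / f"{name}.jsonl")
        assert (tmp_path / "a.jsonl").read_bytes() == (tmp_path / "b.jsonl").read_bytes()
        assert (tmp_path / "a.truth.jsonl").read_bytes() == (tmp_path / "b.truth.jsonl").read_bytes()

    def test_per_subject_stability_under_n_change(self):
        small = generate_corpus(SyntheticCorpusConfig(n_subjects=3, seed=7))
        large = generate_corpus(SyntheticCorpusConfig(n_subjects=6, seed=7))
        assert large[:3] == small
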