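"""Transcript data model and corpus I/O round trips."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sldscreen import (
    DiarizedDialogue,
    FeatureProfile,
    SubjectRecord,
    TruthAnnotation,
    Utterance,
    filter_included,
    read_corpus,
    write_corpus,
)
from sldscreen.dialogue import normalize_whitespace, truth_sidecar_path
from sldscreen.errors import CorpusParseError, DuplicateUtteranceError


def _dialogue(subject, scenario, texts, truth=None):
    utts = tuple(
        Utterance(index=i, speaker="examiner" if i % 2 == 0 else "patient", text=t)
        for i, t in enumerate(texts)
    )
    return DiarizedDialogue(subject_id=subject, scenario_id=scenario, utterances=utts, truth=truth)


@pytest.fixture
def corpus():
    truth = TruthAnnotation(
        profile=FeatureProfile.from_features({"F1", "F6"}), label=1, planted={"F1": (1,)}
    )
    return [
        SubjectRecord(
            subject_id="alpha",
            dialogues=(
                _dialogue("alpha", "S3", ["What is in the picture?", "A récit of naïve clichés — done."], truth),
                _dialogue("alpha", "S4", ["How was your trip?", "Fine."]),
            ),
            a4_score=1,
        ),
        SubjectRecord(
            subject_id="beta",
            dialogues=(_dialogue("beta", "S3", ["Tell me more.", "Backslash \\\\ and quotes \"ok\"."]),),
        ),
    ]


class TestModelValidation:
    def test_whitespace_normalization(self):
        assert normalize_whitespace("  a \t b \n  c ") == "a b c"
        u = Utterance(index=0, speaker="patient", text="  hello\n world  ")
        assert u.text == "hello world"

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            Utterance(index=0, speaker="patient", text="   \n ")

    def test_nonconsecutive_indices_rejected(self):
        with pytest.raises(ValueError):
            DiarizedDialogue(
                subject_id="x",
                scenario_id="S3",
                utterances=(Utterance(index=1, speaker="patient", text="hi"),),
            )

    def test_duplicate_scenario_rejected(self):
        d = _dialogue("x", "S3", ["a", "b"])
        with pytest.raises(ValueError):
            SubjectRecord(subject_id="x", dialogues=(d, d))


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["jsonl", "tsv"])
    def test_lossless_round_trip(self, corpus, dialect, tmp_path):
        path = tmp_path / f"corpus.{dialect}"
        write_corpus(corpus, path, dialect)
        assert read_corpus(path, dialect) == corpus

    def test_truth_annotations_preserved(self, corpus, tmp_path):
        path = tmp_path / "c.jsonl"
        write_corpus(corpus, path)
        assert truth_sidecar_path(path).exists()
        back = read_corpus(path)
        assert back[0].dialogues[0].truth == corpus[0].dialogues[0].truth
        assert back[0].a4_score == 1 and back[1].a4_score is None

    @pytest.mark.parametrize("dialect", ["jsonl", "tsv"])
    def test_unicode_preserved(self, corpus, dialect, tmp_path):
        path = tmp_path / f"u.{dialect}"
        write_corpus(corpus, path, dialect)
        text = read_corpus(path, dialect)[0].dialogues[0].utterances[1].text
        assert text == "A récit of naïve clichés — done."

    @given(
        texts=st.lists(
            st.text(
                alphabet=st.characters(
                    codec="utf-8", exclude_categories=("Cs", "Cc"), exclude_characters="\\"
                ),
                min_size=1,
                max_size=30,
            ).filter(lambda t: normalize_whitespace(t)),
            min_size=1,
            max_size=6,
        ),
        dialect=st.sampled_from(["jsonl", "tsv"]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip_random_text(self, texts, dialect, tmp_path_factory):
        corpus = [SubjectRecord(subject_id="s", dialogues=(_dialogue("s", "S5", texts),))]
        path = tmp_path_factory.mktemp("rt") / "c.dat"
        write_corpus(corpus, path, dialect)
        assert read_corpus(path, dialect) == corpus


class TestReadErrors:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert read_corpus(path) == []

    def test_unknown_speaker_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        rows = [
            {"subject_id": "s", "scenario_id": "S3", "index": 0, "speaker": "examiner", "text": "hi"},
            {"subject_id": "s", "scenario_id": "S3", "index": 1, "speaker": "narrator", "text": "yo"},
        ]
        path.write_text("\n".join(json.dumps(r) for r in rows))
        with pytest.raises(CorpusParseError, match="line 2"):
            read_corpus(path)

    def test_unknown_scenario_rejected(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(
            json.dumps({"subject_id": "s", "scenario_id": "S99", "index": 0, "speaker": "E", "text": "hi"})
        )
        with pytest.raises(CorpusParseError, match="line 1"):
            read_corpus(path)

    def test_duplicate_utterance(self, tmp_path):
        path = tmp_path / "dup.jsonl"
        row = {"subject_id": "s", "scenario_id": "S3", "index": 0, "speaker": "E", "text": "hi"}
        path.write_text(json.dumps(row) + "\n" + json.dumps(row))
        with pytest.raises(DuplicateUtteranceError):
            read_corpus(path)

    def test_malformed_json_names_line(self, tmp_path):
        path = tmp_path / "mal.jsonl"
        path.write_text('{"subject_id": "s"}\nnot json at all {{{\n')
        with pytest.raises(CorpusParseError, match="line"):
            read_corpus(path)

    def test_speaker_aliases_accepted(self, tmp_path):
        path = tmp_path / "alias.jsonl"
        rows = [
            {"subject_id": "s", "scenario_id": "S3", "index": 0, "speaker": "E", "text": "q"},
            {"subject_id": "s", "scenario_id": "S3", "index": 1, "speaker": "Patient", "text": "a"},
        ]
        path.write_text("\n".join(json.dumps(r) for r in rows))
        (rec,) = read_corpus(path)
        assert [u.speaker for u in rec.dialogues[0].utterances] == ["examiner", "patient"]


class TestFilterIncluded:
    def test_excluded_scenarios_dropped(self):
        rec = SubjectRecord(
            subject_id="s",
            dialogues=tuple(_dialogue("s", sc, ["q", "a"]) for sc in ("S1", "S3", "S10")),
        )
        (kept,) = filter_included([rec])
        assert [d.scenario_id for d in kept.dialogues] == ["S3"]

    def test_subject_with_only_excluded_is_dropped_with_warning(self):
        rec = SubjectRecord(subject_id="only-s2", dialogues=(_dialogue("only-s2", "S2", ["q", "a"]),))
        with pytest.warns(UserWarning, match="only-s2"):
            assert filter_included([rec]) == []

    def test_full_module_subject_keeps_eleven(self):
        rec = SubjectRecord(
            subject_id="s",
            dialogues=tuple(_dialogue("s", f"S{k}", ["q", "a"]) for k in range(1, 16)),
        )
        (kept,) = filter_included([rec])
        assert len(kept.dialogues) == 11

    def test_idempotent(self, small_corpus):
        once = filter_included(small_corpus)
        assert filter_included(once) == once
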