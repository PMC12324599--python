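# sldscreen

Screening of autism-associated **social language disorders (SLDs)** from
diarized examiner–patient dialogues, following the structure of ADOS-2
Module 4 (the module for verbally fluent adolescents and adults).

Adults on the autism spectrum often show subtle but diagnostically telling
language patterns — echolalia, pronoun reversal, stereotyped media quoting,
clichéd substitutions for direct answers. Clinically these are summarized by
the ADOS-2 item A4 ("Stereotyped/Idiosyncratic Use of Words or Phrases",
scored 0–3). `sldscreen` implements a transparent, rule-based screening
pipeline over transcripts of the 15 Module 4 scenario tasks (S1–S15, of
which the 11 dialogic ones are analyzed):

1. **Transcript model** — diarized, scenario-segmented dialogues
   (examiner/patient roles) in JSON-lines or TSV, with a lossless round trip.
2. **Prompt engine** — two structured prompts per dialogue: a yes/no SLD
   screening question, and a multi-label question asking which of the **ten
   deficit features** F1–F10 are observed, with the feature taxonomy
   injected as a knowledge block.
3. **Pluggable detector** — a deterministic, offline *reference detector*
   (surface rules + phrase lexicons) used throughout the test suite, plus
   interface-only adapters for live LLM APIs (OpenAI, Gemini).
4. **Rule-based A4 classifier** — at scenario level, with the detected
   feature set *F*:

   - rule (a): if *F* contains a **critical** feature (default F1 Echoic
     Repetition or F9 Stereotyped Media Quoting) → A4 > 0 (label 1);
   - rule (b): else if |*F* \ critical| > 2 → A4 > 0 (label 1);
   - rule (c): else → A4 = 0 (label 0);

   and at subject level, label 1 iff **any** scenario is positive.
5. **Synthetic corpus generator** — feature profiles drawn from a **probit
   copula** (latent z ~ N(0, R), presence_j = 1 iff z_j < Φ⁻¹(p_j)) so the
   configured per-(scenario, feature) prevalences hold exactly in
   distribution, then rendered into template dialogues by per-feature
   injectors that are co-designed with the reference detector.
6. **Analytics & evaluation** — pairwise phi/Pearson correlations between
   binary features, per-scenario prevalence tables, detection-count
   comparisons, confusion-matrix metrics (accuracy, PPV, sensitivity,
   F1 = harmonic mean of PPV and sensitivity), a five-subset
   leave-one-subset-out fold harness with pooled metrics, and a
   diarization-error audit that flips speaker roles and measures the false
   positives this induces in the full pipeline.

The reference detector and generator form a *detectability contract* on
synthetic data (per-feature sensitivity/specificity ≥ 0.95); they make the
pipeline testable end to end offline and are **not** a claim of clinical
validity. See `docs/methods.md` for the model, its parameters and its
limitations.

The two core stages are scikit-learn estimators and compose with sklearn
tooling: `FeatureRuleDetector` (dialogues → n×10 binary feature matrix) and
`RuleBasedA4Classifier` (feature matrix → binary A4 labels).

## Worked example

```python
from sldscreen import (
    SyntheticCorpusConfig, generate_corpus, screen_corpus,
    compute_metrics, prevalence_by_scenario,
)

records = generate_corpus(SyntheticCorpusConfig(n_subjects=6, seed=42))
verdicts, diagnoses = screen_corpus(records)   # reference detector

for d in diagnoses[:1]:
    fired = sorted(sc for sc, r in d.rule_fired.items() if r != "none")
    print(f"{d.subject_id}: label={d.label}  positive scenarios={fired}")

truth = [int(rec.a4_score > 0) for rec in records]
report = compute_metrics([d.label for d in diagnoses], truth)
print("accuracy=%.3f ppv=%.3f sensitivity=%.3f f1=%.3f" % (
    report.accuracy, report.ppv, report.sensitivity, report.f1))

print(prevalence_by_scenario(records).values.loc[["S3", "S9"], ["F1", "F2", "F6"]].round(2))
```

prints

```
sub-001: label=1  positive scenarios=['S11', 'S12', 'S13', 'S14', 'S15', 'S3', 'S4', 'S6', 'S7', 'S9']
accuracy=1.000 ppv=1.000 sensitivity=1.000 f1=1.000
      F1    F2    F6
S3  0.50  0.33  0.33
S9  0.83  0.50  0.33
```

`sub-001` is screened positive because at least one scenario verdict fired a
rule (here many did, under the default prevalences). On clean synthetic
transcripts the reference detector recovers the planted truth exactly, so
all four metrics are 1.0 — the interesting degradations come from the
diarization audit (`sldscreen audit-diarization`), where role-swap noise
creates false positives. The prevalence rows are the empirical per-scenario
feature rates of this 6-subject corpus.

One dialogue from that corpus, with a planted echo (F1):

```
E: Can you describe what is happening in this picture?
P: Not very often, maybe once a month.
E: What usually happens on a typical day?
P: what usually happens on a typical day?
```

## Command line

```bash
sldscreen simulate --out corpus.jsonl --n-subjects 20 --seed 1
sldscreen corpus validate corpus.jsonl
sldscreen screen corpus.jsonl --out diagnoses.jsonl --verdicts-out verdicts.jsonl
sldscreen evaluate diagnoses.jsonl corpus.jsonl --out report.json
sldscreen analyze prevalence corpus.jsonl --out prevalence.csv
sldscreen audit-diarization corpus.jsonl --out sweep.csv --swap 0.0:1.0:0.25
sldscreen knowledge show features
```

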