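# Methods

This note documents the models and procedures implemented in `sldscreen`,
the choices made where the design was genuinely open, and what the passing
test suite does and does not establish.

## The screening problem

ADOS-2 Module 4 sessions consist of 15 scenario tasks (S1–S15). Eleven of
them are direct examiner–patient dialogues; the construction task (S1), the
story-from-a-book task (S2), the demonstration task (S8) and the break
(S10) involve no interactive speech and are excluded from analysis. Within
a dialogue, ten unconventional language patterns (F1–F10: echoic
repetition, unconventional content, pronoun displacement, incongruous humor
timing, formalistic language use, superfluous phrase attachment, excessive
social phrasing, monotone social expression, stereotyped media quoting,
clichéd verbal substitutions) are treated as binary presence indicators.
The clinical target is the binarized A4 item: A4 = 0 (no notable
stereotyped/idiosyncratic language) versus A4 > 0.

## Rule-based A4 classification

At scenario level the detected feature set F is classified by three ordered
rules: (a) any *critical* feature present → label 1; (b) otherwise, more
than `cumulative_threshold` *non-critical* features present → label 1;
(c) otherwise label 0. At subject level the diagnosis is the OR over
scenario labels.

Open choices, resolved as follows:

* **Critical set = {F1, F9}.** Only echoic repetition and stereotyped media
  quoting are ever named as severe-on-their-own; the set is a parameter
  (`critical_features`) rather than a constant, since a clinic may weight
  other features as severe.
* **"More than two" = strictly greater than two** (≥ 3 non-critical
  features). The threshold is exposed (`cumulative_threshold=2`) because
  the quantifier is the only stated cut.
* **Rule (b) counts non-critical features only.** Critical features already
  fire rule (a); counting them twice would make the rules non-orthogonal.
* **Per-scenario application, then OR-aggregation.** Rules are applied to
  each scenario's feature set, not to features pooled across scenarios;
  pooling would let three features scattered over eleven dialogues flag a
  subject who never produced more than one anomaly in a conversation.

The classifier is monotone: adding a feature can never turn a positive
scenario (or subject) negative. This is asserted exhaustively against an
independent brute-force restatement of the rules over all 2^10 feature sets.

## Synthetic corpus

### Feature profiles: probit copula

For scenario s, subject i draws a latent vector z ~ N(0, R) with R a
10×10 correlation matrix (unit diagonal, PSD; default identity) and sets
`presence_j = 1 iff z_j < Φ⁻¹(p_sj)` where `p_sj` is the per-(scenario,
feature) prevalence. This preserves the marginals exactly in distribution
while R induces dependence between features. The induced phi coefficient
between two indicators is a monotone but *attenuated* function of the
latent correlation (e.g. latent ρ = 0.8 at p = 0.5 marginals yields
phi = (2/π)·arcsin(0.8) ≈ 0.59); no calibration of R to any empirically
reported correlation matrix is attempted.

The default prevalence table ships with the package (rows = the 11 included
scenarios, columns = F1–F10, values 0.02–0.64). Excluded scenarios have no
default row; generating them requires user-supplied prevalences.

Degenerate inputs are well defined: p = 0 gives Φ⁻¹(0) = −∞ (feature never
planted), p = 1 gives +∞ (always planted). R is validated symmetric with
unit diagonal and eigenvalues ≥ −1e−9; the sampling factor is the
eigendecomposition square root with negative eigenvalues clipped at zero.

### Dialogue rendering and injectors

A dialogue is `k` question–answer pairs (`dialogue_length=(4, 7)`,
uniformly drawn; a few minutes of scenario conversation) of
scenario-flavored examiner questions and bland patient answers, closed by a
fixed three-line examiner coda. For each planted feature, an injector
rewrites or appends patient utterances with that feature's canonical
surface pattern (echoing the previous question for F1; odd-content,
archaic, filler, courtesy, media-quote and cliché phrases from packaged
lexicons for F2/F5/F6/F7/F9/F10; a pronoun-frame sentence for F3; a joke
marker on a serious topic for F4; a repeated social phrase plus a flat-tone
marker for F8). The two replacement injectors (F5, F10) reserve distinct
answer slots up front so no injection ever erases another; truth
annotations store the profile, the rule-consistent scenario label and the
planted utterance indices.

The lower bound of `dialogue_length` is 3 so the replacement injectors
always have distinct slots.

Randomness is hierarchical: a single seed spawns independent
`(kind, subject, scenario)` streams, so corpora are byte-reproducible and
per-subject data are invariant to `n_subjects`.

### What the generator does and does not emulate

It emulates: scenario segmentation, role diarization, per-scenario feature
prevalences, tunable co-occurrence, and textual surface patterns detectable
by rule. It does **not** emulate real ASD speech distributions, disfluency,
ASR noise, topic coherence or prosody. F8 (monotone intonation) has no
textual surface at all in real transcripts; it is represented by a
synthetic marker token `(in a flat tone)` purely so the feature remains
exercisable. Consequently, a passing suite shows the *pipeline machinery*
is correct (prompts, parsing, rules, metrics, I/O), not that the reference
detector would detect these features in clinical speech.

## Reference detector

The reference detector operationalizes each feature definition as a
deterministic surface rule over patient utterances (lexicon hits on a
normalized form: lowercased, punctuation and apostrophes stripped;
pronoun-frame regex for F3; quote-span or media-lexicon for F9; etc.). Two
judgment calls in the echo rule (F1):

* comparison is **person-deixis-insensitive** — first/second-person words
  collapse to a placeholder, so "do **I** have some friends?" counts as an
  echo of "do **you** have some friends?", which is how clinicians read
  immediate echolalia;
* **leading discourse fillers** (uh, um, okay, so, …) are stripped from
  both sides, and a minimum of 5 normalized tokens (`echo_min_tokens`)
  avoids flagging trivial "Yeah." echoes.

The detector's yes/no screening answer is "Yes" exactly when its own
feature rules return a non-empty set, so the two prompt kinds cannot
disagree. Lexicons are plain text files, user-extensible.

Live-API adapters (OpenAI, Gemini) share the one-call interface with
temperature-0 defaults; they import their SDKs lazily and are outside the
offline test surface.

## Evaluation harness

Metrics are the usual confusion-matrix fractions; F1 is the harmonic mean
of PPV and sensitivity (algebraically 2TP/(2TP+FP+FN), asserted as a
property). Zero-denominator ratios are reported as `None` with an explicit
`undefined` flag and a warning — coercing them to 0 or 1 would silently
distort pooled comparisons.

The fold harness shuffles units with a seeded RNG and assigns them
round-robin to k = 5 folds, so sizes differ by at most one (463 samples
split 93/93/93/92/92). Grouping defaults to *subject level* to prevent a
subject's scenarios from straddling train and test folds (relevant when
subjects are assessed twice); sample-level grouping is available. Pooled
evaluation concatenates the per-fold test predictions into one vector
before computing metrics (not a macro average), and verifies exact
coverage. The rule-based detector path is training-free and ignores folds;
the harness exists for protocol fidelity and any future supervised
baseline.

### Diarization audit

`perturb_roles` flips the speaker role of `round(f·n)` seeded-random
utterances (optionally merging swapped turns into same-role neighbours,
mimicking diarizer segment merging); truth annotations are untouched. The
synthetic examiner coda deliberately contains a filler tag, a quoted media
line and a courtesy phrase — innocuous as examiner speech, since the
detector only scans patient turns, but misattributed to the patient they
produce spurious F6/F9/F7 detections. The audit therefore reproduces the
characteristic failure mode of role-swap diarization errors: on a corpus
of true-negative subjects, the pipeline's false-positive count grows
monotonically (in seed-averaged trend) with the swap fraction.

## Numerical and statistical choices

* Pearson-on-binary equals the phi coefficient; pairs involving a
  zero-variance feature are undefined (NaN + mask), never 0. No
  multiple-testing correction is applied to reported coefficients.
* Prevalence recovery tests: a single configured entry is checked within 3
  binomial standard errors at n = 2000. The *joint* check over all 110
  table cells uses a Bonferroni-adjusted z (family-wise error held at the
  single-entry 3σ level), because a per-entry 3-SE band applied 110 times
  rejects a correct sampler about a quarter of the time.
* Problem sizes in the test suite (8–25 subjects for pipeline contracts,
  2000 profiles per scenario for marginal recovery, 3000–5000 for
  correlation recovery) were chosen to make the binomial error bars small
  relative to the effects being checked.
* Parsed answers are handled with an explicit ambiguity policy: the default
  raises on answers with no (or contradictory) verdict tokens; an opt-in
  pessimistic mode maps ambiguity to the negative outcome with a warning.

## Known limitations

* The reference detector is one defensible operationalization of prose
  feature definitions; real LLM or clinician judgments will differ,
  especially for context-dependent features (F4, F7).
* Template dialogues are deliberately simple; prevalence and correlation
  analytics on synthetic corpora validate the estimators, not any clinical
  distribution.
* Scenario-level labels are binary only; ordinal A4 severity (1/2/3) is
  out of scope.
* The TSV dialect escapes tabs/newlines defensively, but utterance text is
  whitespace-normalized on ingestion, so intra-utterance line structure is
  not preserved by design.
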