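# Methods

`riskfuse` implements a tier-stratified, multi-modal text-classification
pipeline for matched case-control cohorts of clinical notes. This note
documents the model, its assumptions, the parameters that matter, the
synthetic-data generator that stands in for restricted EHR data, and the
numerical and design choices that were genuinely open.

## Design and model

**Cohort.** Each patient carries a baseline risk percentile in [1, 100]
(1 = riskiest) produced by an upstream structured-data model. The percentile
does two jobs: it defines the risk tier — high (percentile 1), moderate
(2–24), low (25–100) — and it is the matching variable. Every case is paired
with `k` controls (default 5) sharing its exact percentile and, when known,
facility; controls inherit the case's index date so follow-up windows are
identical. Because of this matching, a patient-level AUC above 0.50 measures
discrimination *beyond* the baseline score, not beyond chance. Match balance
on any other covariate is diagnosed with the standardized mean difference,
`|m₁ − m₀| / √((v₁ + v₀)/2)` (proportion variance `p(1−p)` for binaries),
labeled at the conventional 0.2 / 0.5 / 0.8 cut points.

**Note window.** Only notes dated 5–30 whole days before the index date are
analyzed (both bounds inclusive). Notes within 0–4 days are discarded —
records entered around the index event can leak outcome information (e.g.
misdated post-mortem documentation). The day-5 boundary is retained: the
exclusion interval is read as [0, 5) so that the retained interval is exactly
the named 5–30 days.

**Featurization.** Two views of each note:

- *Open vocabulary (count features).* Text is lowercased, split on every
  non-alphanumeric character (digits kept, clinical acronyms left as-is),
  stopwords removed (default list: scikit-learn's English inventory), and
  unigrams plus adjacent bigrams formed over the surviving sequence — so
  bigrams can span a removed stopword. A vocabulary is fitted on the
  *training* notes of a tier only: a term survives iff it occurs in at least
  `min_df` documents (default 100) and at most `max_df` of them (default
  0.9, read strictly: df ≤ ⌊0.9·n⌋ survives). Documents become sparse count
  rows; a smoothed-idf TF-IDF re-weighting
  (`idf = ln((1+n)/(1+df)) + 1`, rows L2-normalized, fit-time df frozen) is
  available but off by default — plain counts performed at least as well in
  the regimes exercised here.
- *Closed vocabulary (semantic features).* Each lexicon category is a set of
  lowercase unigrams tied to a psychosocial construct. A note's score is the
  proportion of kept tokens matching the set, in [0, 1]; empty notes score 0.
  Each category may emit negation-controlled variants `<cat>_neg_k`: a match
  is suppressed when a negation cue (no, not, never, denies, denied,
  without) occurs within the `k` raw tokens preceding it. The lookback scans
  the *pre-stopword* sequence, because cues like "not" sit on the stopword
  list and would otherwise be invisible; the score denominator remains the
  kept-token count. Multiword dictionary entries and word-sense
  disambiguation are out of scope; polarity is metadata, not a sign flip.

**Fusion and the α/β weighting.** The two matrices are merged column-wise,
aligned by note id, names prefixed by their set tag. Count features vastly
outnumber semantic features, so under uniform split-candidate sampling a
boosted tree almost never evaluates a semantic column. Count features keep
selection weight 1 and every semantic feature gets

    w_semantic = (n_count / n_semantic) · α .

Summed over each set, semantic candidates then make up a fraction
β = α/(α+1) of the sampling mass — β is the reporting axis. The default
sweep is α ∈ {0.01, 0.03, 0.06, 0.10, 0.30, 0.60, 1.00, 2.50, 5.00}
(β ≈ 0.01…0.83). Weights are handed to the learner un-normalized; they bias
*which* columns enter a node's candidate set whenever column subsampling is
active, so the weighting is only operative with `colsample_* < 1` (default
`colsample_bynode = 0.8`).

**Learner.** XGBoost binary classifiers trained on *note-level* rows (far
more numerous than patients). Nothing is normalized and missing values stay
missing — trees handle both natively. Class imbalance from 1:k matching is
offset by `scale_pos_weight = n_control/n_case` (configurable off). Training
is single-threaded with the exact histogram method, so fixed seeds give
byte-identical models.

**Partitioning.** Patients — never notes — are assigned 64 / 16 / 20% to
train / validation / test. All of a patient's notes inherit the patient's
partition. The default sampling unit is the *match group*: a case and its
matched controls land in the same partition. This matters at desk scale:
with only a handful of groups per percentile value, scattering a matched set
across partitions lets a note-level learner anti-learn held-out status from
per-percentile training composition (a test control shares its exact
percentile with its own case in training), biasing the covariate-only null
model well below AUC 0.5. Keeping matched sets intact — standard practice in
matched designs — removes the artifact; with equal group sizes it makes any
score that is a function of the matching variable score exactly 0.5, which
is precisely what the matching-validation check asserts. Per-patient
assignment remains available (`unit="patient"`).

**Hyperparameter search.** A randomized search (default 100 draws over tree
depth 2–10, log-uniform learning rate 0.01–0.3, 50–500 trees, subsample and
column-sample 0.5–1.0, min child weight 1–10) ranks configurations by mean
patient-level AUC under patient-grouped 5-fold CV on the training partition;
the top few (default 5) are refit on the full training partition and the one
with the best patient-level AUC on the withheld validation partition wins.
The CV pass does coarse ranking; the validation partition makes the final
call — reconciling a grid search "with 5-fold CV" with selection "on a
withheld validation set" in one procedure.

**Evaluation.** A patient's score is the arithmetic mean of their note
probabilities. AUC is the Wilcoxon–Mann–Whitney concordance with ties
counted ½ (identical to trapezoidal ROC integration; verified against an
independent implementation in the tests). Confidence intervals come from a
status-stratified non-parametric bootstrap over patients (default 1000
resamples, 95% percentile interval); the resampling unit is the patient
because the outcome lives there. Two models are called significantly
different iff their intervals do not overlap. The thresholded battery
(Brier, accuracy, precision/PPV, recall, specificity, NPV, F1) uses a fixed
0.5 cutoff; with matched imbalance this often yields zero predicted
positives at the patient level, so empty-denominator ratios are reported as
0 and flagged rather than erroring.

## Synthetic data

Real corpora of this design are access-restricted, so the generator
reproduces the structure every stage depends on:

- **Matched groups**: `n_cases` cases, each with `controls_per_case`
  (default 5) controls sharing percentile, facility and index date.
  Percentiles follow the tier (high → 1, moderate → uniform 2–24, low →
  uniform 25–100); the default tier mix (14 / 50 / 36%) follows the case
  composition observed in cohorts of this design.
- **Note volumes**: per-patient counts are negative-binomial, moment-matched
  to the per-tier, per-status means/SDs of the emulated setting (high
  37.9/53.9 case vs 40.0/82.3 control; moderate 15.0/32.7 vs 12.2/40.9; low
  9.1/18.5 vs 7.0/19.0) and truncated at 1 (the truncation lifts means by a
  few percent — accepted). The SDs are roughly twice the means, which rules
  out Poisson. Dates are uniform 5–30 days pre-index, plus ~25% decoy notes
  at 0–4 or 31–60 days to exercise the window filter.
- **Text**: Zipf-distributed background tokens (exponent 1.1) over a
  tier-specific vocabulary (moderate largest, low smallest), note lengths
  negative-binomial (default mean 200, SD 150 tokens). Sprinkled through are
  negation cues, decoy lexicon terms, and two reserved signal sets: lexicon
  ("semantic") terms and out-of-lexicon ("count") tokens, each at a base
  per-token rate (default 0.005 across 40 terms). `signal_mode` multiplies
  the active set's rate by `effect_size` in case notes — frequency
  multiplication, never case-exclusive tokens, so classification stays
  non-trivial. Under `signal_mode="none"` the arms are exchangeable.
- **Truth record**: planted terms, mode and effect size are emitted
  alongside the corpus for verification.

What the generator does *not* emulate: real clinical language, templated
notes, topic structure, coded PHI, temporal drift, or correlations between
note content and structured covariates. Passing tests therefore demonstrate
that the pipeline recovers signal of the planted kind under realistic
sparsity and imbalance — not that any particular feature set wins on real
notes.

## Problem sizes used in tests

The checks run at deliberately modest scale, chosen so the full suite
completes in minutes while keeping every mechanism operative: the
matching-null check uses 200 cases (1200 patients, ≈25k notes); the
signal-recovery checks use 80 cases with 3 controls in a single tier
(≈2.5k analyzed notes) with `min_df` rescaled to the corpus (30 where signal
must survive the filter, 150 where rare semantic signal must be excluded
from the open vocabulary); the split contract is checked at 1002 patients.
The α-sweep monotonicity check instruments split-feature shares on a
label-free noise matrix with `colsample_bynode=0.2`, where sampling
propensity — not information — drives feature usage.

## Numerical choices

- **β reporting**: `beta_table` computes α/(α+1) in decimal arithmetic with
  half-up rounding. Binary floats misround exact halves (0.60/1.60 is
  exactly 0.375, but its float64 image rounds to 0.37); the published
  two-decimal axis assumes conventional rounding of the exact value.
- **max_df boundary**: "more than 90% of documents" is strict; df equal to
  ⌊0.9·n⌋ survives (a 1e-9 slack guards the floor against float error).
- **AUC ties** count exactly ½ via midranks (the exact Mann–Whitney
  estimator), so heavy score ties — common with matched groups — behave
  deterministically.
- **Degenerate inputs**: empty documents score 0 on every lexicon category;
  an all-filtered vocabulary is a warning, not an error (downstream count
  models are skipped with an explicit report entry); single-class training
  or validation labels are rejected; zero-denominator battery metrics are
  flagged, not NaN.
- **Determinism**: every stochastic step (matching, splitting, generation,
  search, bootstrap) takes an explicit seed; reruns are byte-identical,
  including report JSON.

## Known limitations

- The negation scheme is a fixed lookback window with a small cue list; it
  does not handle scope, double negation, or cues split by the tokenizer
  (e.g. the "n't" cue cannot match because the tokenizer splits it).
- Semantic scoring supports unigram dictionary entries only.
- Probabilities are not calibrated; only ranks (AUC) and fixed-threshold
  metrics are reported.
- The search's CV/validation reconciliation is one defensible reading of a
  procedure that can be described several ways; both knobs are exposed.
- With very small tiers, partitions can lack a class; such tiers are
  reported as skipped rather than silently dropped.
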