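# Methods

## Problem and model

`dmfind` identifies diabetes-mellitus (DM) cases from encounter-based
clinical notes when structured diagnosis codes are absent or incomplete.
Let *f* be the feature vector extracted from a note's free text and
structured fields, and let *ICD* indicate whether the encounter carries an
ICD-9-CM 249/250 diagnosis code.  The posterior over DM status is split on
the codified flag:

- **Codified branch.** `P(DM=1 | ICD=1) = 1`: a 249/250 code is taken as a
  diagnosis by construction (human prior knowledge, a predetermined
  single-split tree).  Dotted (`250.02`) and undotted billing (`2500`)
  forms are both recognised by their three-character root; ICD-10 codes are
  ignored.
- **Uncodified branch.** `P(DM=1 | ICD=0, f) = T(f)`, the vote fraction of a
  random forest over *f*.  The forest defaults to 500 trees with √p features
  per split and a fixed seed; class probabilities are the fraction of trees
  voting DM, so scores live in [0, 1] with 1.0 reserved for the codified
  branch.

A patient is classified DM if **any** note scores at or above the cutoff
(closed lower bound, maximising sensitivity at the calibrated point); the
first-positive date is the earliest such encounter.

## Text preprocessing

Notes are collapsed into non-overlapping basic units (paragraphs, sentences,
lines).  Paragraphs split on blank lines; multi-line paragraphs are treated
line-wise so template blocks ("BMI: 31") stay whole; units containing
sentence boundaries are sentence-split.  The boundary detector is rule-based
and pluggable: terminal punctuation followed by whitespace and an
uppercase/digit start, with decimal points protected structurally (a decimal
point is never followed by whitespace) and a small abbreviation list (Dr.,
Mr., vs., e.g., No., …).  The whole-paragraph threshold (200 characters) is
configurable.

Negation and family-history handling is **segment-scoped**: any unit
containing a trigger phrase (whole-word, case-insensitive; multi-word
triggers contiguous) is removed before any feature matching.  The negation
lexicon is a reduced NegEx-style phrase set; the family lexicon covers
kinship words and "family history" phrasings.  Segment scope deliberately
trades recall (an affirmative mention sharing a unit with a negation is
lost) for specificity of what survives, which is the correct trade for a
case-finding tool whose operating point is a PPV floor.

## Knowledge base and features

The controlled vocabulary holds single and dual tokens derived by
tokenising (lowercase; punctuation stripped except intra-word hyphens;
digits retained so "type 2" survives), combining into unigrams plus adjacent
bigrams, and removing any candidate containing a stop word.  The shipped
default (~102 terms) applies this construction to the ICD-9-CM 249/250
rubric descriptions plus common DM clinical phrases; the lexicon file is a
first-class input and a site can substitute a full terminology-derived list.
The medication lexicon defaults to 24 generic antidiabetic names.

Features are: binary per-term and per-medication indicators (whole-word
phrase matches on the cleaned text), one-hot risk-factor categories, age in
years, and one-hot sex.  Risk factors are extracted by ordered regular
expressions with first-match precedence:

- **BMI** — explicit value, or derived from height/weight with explicit
  units (m/cm/in, kg/lb; bare numbers are skipped as ambiguous); WHO
  classes with half-open intervals: underweight < 18.5 ≤ normal < 25 ≤
  overweight < 30 ≤ obesity.  Implausible values (outside 5–120 kg/m²) are
  discarded.
- **High blood pressure** — phrase mentions, or a reading with systolic
  ≥ 140 or diastolic ≥ 90 mmHg.
- **Smoking** {never, former, current}; **alcohol use** {none, use,
  disorder}; **clinical history of DM** {present} (the "history of
  diabetes" phrase family is a feature, not a direct label).

Missing age is imputed with the corpus median (fallback 50); missing sex is
an all-zero one-hot.

## Training

Positives are all codified notes; negatives an equal-size seeded random
sample of uncodified notes (all of them, with a warning, if fewer exist).
Features are screened per column by a two-sided Mann-Whitney rank-sum test
at α = .05.  Small samples (whenever C(n, n₁) ≤ 2·10⁵) use the exact
permutation null of the rank sum, computed by dynamic programming over
(subset size, doubled rank sum) with midrank ties; two-sided p is the
doubled smaller tail, capped at 1 — under heavy ties the permutation null is
asymmetric, so the |deviation| form is not well defined.  Larger samples use
the tie-corrected normal approximation with continuity correction.
Constant columns get p = 1 and are never selected.

**Iterative refinement** emulates the curator loop: training negatives whose
**out-of-bag** class probability reaches the flag threshold (default 0.5)
are adjudicated by a pluggable truth oracle (human chart review in
production; synthetic ground truth in tests); confirmed DM notes move to the
positive class and the forest is refit, stopping at a fixed point or after
`max_iterations` (default 5) passes.  Out-of-bag scoring matters: an
in-sample forest memorizes its own training labels and would never flag a
mislabeled negative.

Feature importance is reported two ways: permutation importance (mean
decrease in accuracy over R = 10 seeded column permutations, scaled by the
standard deviation of the decreases; zero-SD features fall back to the raw
mean and are flagged) and the ensemble's total Gini impurity decrease.

## Cutoff calibration

Given prevalence π and PPV target P\*, the pairs (sensitivity s,
specificity) achieving exactly P\* lie on the straight line

    spec_min(s) = 1 − s·π·(1−P*) / (P*·(1−π)),

the algebraic solution of P\* = sπ / (sπ + (1−spec)(1−π)).  The cutoff is
the ROC point (one point per distinct score; trapezoidal AUC) of maximal
sensitivity on or above this line — equivalently the first intersection of
the line with the ROC curve walking from the (0, 1) corner; sensitivity
ties break toward higher specificity.  Because a step-function ROC can touch
the line along a segment, the maximal-sensitivity formulation is the
well-defined statement of "first intersection".  π defaults to the
empirical prevalence of the calibration draw (a 100 DM / 500 non-DM gold
standard gives π = 1/6) and is an explicit parameter.  The numeric cutoff
is data-dependent and never hard-coded.  An unattainable target raises an
error reporting the best achievable PPV.

## Evaluation

Confusion metrics are exact ratios (PPV, NPV, sensitivity, specificity); a
zero denominator yields an undefined (None) metric, never 0.  Interval
estimates use the Wilson score method, standard for small-n proportions
(for 62/65 it gives [.873, .984]).  Case-finding yield is
100·additional/codified.  The temporal comparison computes lead = first
ICD date − first NLP-positive date per patient with both dates; strictly
positive leads count as NLP-earlier, the mean is over positive leads, and
"3 months or more" is operationalised as ≥ 90 days.  The MDS training
diagnostic is classical metric scaling (double-centered eigendecomposition
of squared distances) on pairwise Jaccard distances of the binary feature
vectors (the distance is configurable; the binary-vector Jaccard choice is
this package's).

## Synthetic corpus

The generator draws, per patient: DM status (Bernoulli, prevalence .10),
facility (uniform over 8; a categorical attribute enabling facility-split
blind testing), age (DM: N(66, 10); non-DM: N(48, 16), clipped to 18–95),
sex, and 1 + Poisson(0.8) notes with sorted uniform dates over one year.
Note text is assembled from a fixed template bank with slot filling —
controllability over realism.  DM notes emit affirmative DM sentences with
probability .75 per note (echoing that roughly two-thirds of uncodified DM
cases carry a diabetes history in their notes), complication sentences .25,
history-of-DM sentences .35, and 1–2 antidiabetic medications .50; risk
profiles skew obese/hypertensive.  Non-DM notes emit negated DM phrases
with probability .15 and family-history phrases .10 (family phrases occur
for DM patients too); vitals lines exercise the BMI/height-weight paths and
decimal-point boundary hazards.  A .70 fraction of DM patients is codified:
the code lands on the first DM-text encounter with probability .6954, else
a geometric lag with mean 48 days generates the coding encounter itself (a
brief follow-up note carrying the code, capped at the date-range end).
All randomness flows through one seeded generator; a fixed seed yields a
byte-identical serialized corpus.

What the generator does **not** emulate: realistic linguistic variety,
misspellings, copy-forward duplication, window-scoped negation ("no chest
pain but diabetic"), conflicting risk-factor statements, ICD-10 mixtures,
or inter-facility documentation drift.  Passing the end-to-end tests
therefore demonstrates that the pipeline's machinery is correct under the
stated statistical structure, not that the shipped default lexicon would
reach the same operating characteristics on real clinical text.

## Problem sizes and numerics

The end-to-end recovery run uses 5000 patients (~10,800 notes), a 4/4
facility split, 500 trees, and a 100/500 calibration draw; it completes in
well under a minute on one CPU, and unit tests use 400–1200-patient
corpora.  Feasibility comparisons in cutoff selection use a 1e-12 slack so
the constraint-line test is exact up to float error; probability bounds and
determinism (fixed seeds everywhere, single-threaded forests) are asserted
by the test suite.  Degenerate inputs are defined errors: empty corpora
score to empty frames, single-class inputs refuse to fit or build ROC
curves, all-identical MDS inputs return zero coordinates with a warning.

## Known limitations

- Segment-scoped negation removes whole units, losing affirmative mentions
  that share a unit with a trigger; bare "no"/"not" triggers are aggressive
  by design (NegEx heritage) and configurable.
- The default vocabulary contains generic tokens (bare numerals from
  "type 2") that match vitals text; these are expected to be removed by the
  statistical screen, not structurally.
- The rule-based sentence splitter approximates part-of-speech-assisted
  boundary detection; it is exposed behind `segment_note` so a model-based
  splitter can replace it.
- Calibration assumes the gold-standard draw is exchangeable with the
  deployment population at the stated prevalence; a mismatched π shifts the
  achieved PPV.
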