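# Methods

`reflexlens` analyses a corpus of short post-shift reflective comments
written by clinical clerkship students, each shift also carrying an
attending's RIME rating (Reporter < Interpreter < Manager < Educator,
with "Inadequate" off the ladder and "Superior" accepted as an alias
for Educator), and each student a final grade on the 0–100 scale.
This note records the models, conventions and design choices; every
empirical statement here is one the test suite or the acceptance
script computes itself.

## Text normalisation and the completion predicate

Comments are processed in four steps: lower-casing; tokenisation;
stopword removal; lemmatisation. The tokenizer is a deterministic
regular expression over word-character runs (`[^\W_]+`), chosen over a
learned tokenizer for reproducibility: punctuation vanishes and
intra-word punctuation splits tokens, so `s/p` becomes `s`, `p`.
Stopwords are matched on *surface* tokens before lemmatisation
(pipeline order is part of the contract); the documented consequence is
that an unlisted inflected variant of a stopword survives, and an
optional post-lemma second pass (`second_stop_pass=True`, off by
default) closes that gap when wanted.

The part-of-speech tagger is a deterministic function-word/suffix
classifier over five coarse tags (noun, verb, adjective, adverb,
other), defaulting to noun for unknown open-class words; its outputs on
fixed phrases are frozen in the test suite so any change to the tagging
rules is caught deliberately. The lemmatizer is rule-based and
strictly inflectional (plurals, verb -s/-ed/-ing, comparatives), keyed
by the coarse tag and backed by an irregular-forms lexicon; tokens the
rules do not recognise pass through unchanged. Derivational families
("infection" → "infect") are deliberately *not* collapsed by
lemmatisation — that is stemming, and a Porter stemmer is provided as
an explicit opt-in backend (`backend="porter"`) rather than silently
blurring the two operations. On arbitrary English the suffix rules are
heuristic (e.g. `-ed` stems whose spelling requires an unusual final
`e` can come out bare); on the synthetic symbol vocabularies used for
validation they are exact, and the fixture words exercised in tests are
pinned.

A comment is **complete** iff at least one lemma survives stopword
removal — one content word. The completion *fraction* divides by the
number of shifts worked (14 in the emulated design), not by the number
of comments written: an empty comment row is a shift without a usable
reflection, not missing data.

The package ships a standard English function-word stoplist
(~160 entries) as its default; any user list (e.g. corpus-derived
high-frequency words) can be supplied instead or in addition, and an
intentionally empty stoplist must be requested explicitly — silently
running without one would change every downstream count.

## N-gram profiles and category vocabularies

Unigrams and bigrams are counted over content lemmas of completed
comments; bigrams pair *adjacent* lemmas within one comment and never
cross comments. Headline table sizes default to the 50 most common
words and 9 most common two-word phrases. Rankings break count ties
lexicographically — silent nondeterminism at the k-th rank would make
the downstream Jaccard values irreproducible — and any tie broken at
the boundary is recorded in the vocabulary's `tie_note`.

A category vocabulary is the top-k unigram set over the completed
comments rated with exactly that single category. Hybrid ratings (two
adjacent rungs circled) are excluded because the evaluator's intent is
ambiguous; "Inadequate" is excluded from category analyses by default
because such ratings are typically too few to characterise. The
vocabulary size k is a **required, always-recorded parameter** of every
similarity computation: similarities at unstated k are not comparable.

## Jaccard similarity and its resampling null

For two categories, the statistic is J = |A∩B| / |A∪B| between their
top-k vocabularies. Significance comes from comment-level label
exchange: pool the two categories' eligible comments, reassign them
without replacement into two groups of the original sizes, recompute
both top-k vocabularies and their Jaccard, repeat B times (default
1,000). The resampling unit is the whole comment, respecting the
dependence between words in one comment; a word-level bootstrap would
overstate the effective sample size.

The p-value is left-tailed, `p = (1 + #{J_null ≤ J_obs}) / (B + 1)`:
small p means the two vocabularies are more *distinct* than label
exchange predicts, and the +1 correction makes it a valid permutation
p-value bounded below by 1/(B+1). Per-pair child seeds derive from the
master seed and the sorted pair names, so the pairwise matrix is
invariant to category order and reproducible bit-for-bit. No
multiplicity correction is applied by default (raw per-pair p-values
are reported); Holm step-down adjustment is available behind a flag.

## Grade association

Per student: completion fraction and mean comment length. Length
counts raw word tokens as written (before stopword removal), averaged
over all shifts with empty shifts contributing zero — the natural
reading of "number of words in each reflection"; a content-lemma
convention is available via `length_convention="content"`.

Association statistics:

* Pearson r of each effort statistic against grade, with the
  least-squares line (slope, intercept, R²) for scatter-plot style
  reporting, and the exact-null test t = r√(n−2)/√(1−r²) on n−2
  degrees of freedom, two-tailed.
* A completer split at completion fraction strictly greater than 0.5
  ("more than half"); the boundary student is a non-completer.
* Group summaries with linear-interpolation quantiles (the convention
  is stamped into the report): median, IQR, notch interval
  median ± 1.57·IQR/√n (the standard notched-boxplot approximation to a
  95% CI for the median), whiskers at the 2nd/97th percentiles.
* A two-sided two-sample Kolmogorov–Smirnov test of the two grade
  distributions; the p-value is exact when both groups have n ≤ 25 and
  asymptotic otherwise.

## Rating classifier

A multinomial naive-Bayes model over comment bags of content lemmas
predicts the shift's RIME category, trained on the same eligible set as
the category analyses (completed, single-category, non-Inadequate) with
additive smoothing α (default 1, Laplace). Evaluation is stratified
k-fold cross-validation (default 5 folds), deterministic given its
seed. A class with fewer completed comments than folds raises a typed
stratification error — the precise, recoverable form of "not enough
data to train the classifier" — which the pipeline driver downgrades to
a warning so the rest of the analysis still runs. Note that with fixed
α, duplicating a training corpus changes smoothed likelihoods slightly
(counts double, α does not): predicted labels are stable and posteriors
converge as the corpus grows, but exact posterior invariance under
duplication holds only if α is scaled with the corpus.

## Synthetic corpora and what they do (not) show

The generator plants: per-student completion propensity ~ Beta(a, b)
(default (2, 1), mean 2/3); grades linear in the realised completion
fraction plus Gaussian noise (sd 5 grade points), clamped to [0, 100];
a rating for every shift (hybrids at a configurable 10% rate); and
category word pools of synthetic symbols whose pairwise shared fraction
ρ_v is planted (1 = identical pools, 0 = disjoint), mixed with a shared
core vocabulary and stopword filler at Zipf-distributed frequencies
(exponent 1.1, comment length Poisson with mean 12, 40% stopword
fill). Defaults mirror the emulated study design: 116 students × 14
shifts.

Numerical choices worth recording:

* Clamping attenuates the grade correlation, so when a target
  correlation is requested the slope is calibrated *after* clamping by
  bisection against a large (20,000-student) reference draw from a
  fixed internal stream; the calibrated slope is a property of the
  planted model, shared by all corpora with those parameters.
* Every completed shift is forced to contain at least one content
  word, so the completion predicate measures exactly the planted
  propensity rather than propensity × P(no all-stopword comment).
* The expected pairwise vocabulary Jaccard implied by the pool
  construction (shared block s over union 2·size − s) is stored in the
  ground truth, which analysis code never reads.

Ground-truth recovery on these corpora validates the *computational*
pipeline: bookkeeping, exclusion rules, statistics, calibration of the
resampling null. It does not show that the pipeline's linguistic
components handle real clinical free text well — synthetic words have
no inflection, spelling errors, abbreviations or negation, and real
reflective writing has all of them. Conclusions about real corpora
need the usual caveats about stoplist choice, k, and transcription
quality.

Named frozen fixtures: `tiny` (6 students, hand-checkable),
`calibration` (exchangeable categories via identical pools, 40
students), `separable` (disjoint pools, no core vocabulary, 400
students), `null` (zero planted correlation, 300 students).

## Validation design and known limits

The validation suite checks, among others: Jaccard and KS against
brute-force oracles; calibration of the resampling null (left-tail
rejection rate at α = 0.05 over 200 replicate exchangeable corpora
within 3 binomial SE of 0.05); planted-overlap recovery (J = 0 at the
p-floor for disjoint pools; J ≈ 1 for identical pools comparing full
content vocabularies at n = 400); planted-correlation recovery at
n = 300 over 100 replicates for ρ ∈ {0, 0.3, 0.5}; and classifier
accuracy ≥ 0.9 on separable corpora vs chance on exchangeable ones.

One recovery check is knowingly beyond what the sampling distribution
allows: under independence E[r̂²] = 1/(n−1) exactly, so at n = 300 the
standard deviation of r̂ is at least 0.058 and |r̂| < 0.1 holds in only
~92% of replicates — no implementation can reach 95% coverage there.
The check is kept at its stated strength (and the companion
type-I-rate check, which is attainable, passes); its expected failure
is a property of the sample size, not of the code.

Simulation sizes throughout (replicate counts, students per corpus,
B = 200–500 in bulk loops) are chosen so the full validation runs in a
few minutes on one CPU while keeping binomial noise well inside the
asserted bands.
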