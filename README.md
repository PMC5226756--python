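# reflexlens

Corpus analytics for reflective writing in clinical training.

Medical clerkships increasingly ask students to write a short free-text
reflection after every shift, while an attending rates the shift on the
RIME ladder (Reporter < Interpreter < Manager < Educator; some
evaluation forms print "Superior" for the top rung, and a hybrid rating
circles two adjacent rungs). `reflexlens` turns a logbook of such
records — per-shift comment text and rating, per-student final grade —
into a reproducible statistical analysis:

* **Normalisation and completion scoring.** Comments are lower-cased,
  tokenised by a deterministic regular expression, stopword-filtered
  and lemmatised (rule-based inflectional lemmatizer; opt-in Porter
  stemmer). A comment is *complete* iff at least one non-stopword word
  survives; a student's completion fraction divides by shifts worked.
* **Vocabulary profiles.** Unigram/bigram frequency tables (bigrams
  never cross comments) and top-k vocabularies per rating category,
  with deterministic lexicographic tie-breaking.
* **Vocabulary similarity with a resampling null.** For each category
  pair, the Jaccard similarity J = |A∩B|/|A∪B| of the two top-k
  vocabularies, with a left-tailed permutation p-value
  p = (1 + #{J_null ≤ J_obs})/(B+1) obtained by reassigning whole
  comments between the two pools without replacement: small p means
  the vocabularies are more distinct than label exchange predicts.
* **Grade association.** Pearson r of completion fraction (and mean
  comment length) against final grade with the t-test
  t = r√(n−2)/√(1−r²); a completer split at fraction > ½ with notched
  boxplot summaries (median ± 1.57·IQR/√n); a two-sample
  Kolmogorov–Smirnov comparison of the two grade distributions.
* **Rating classifier.** Multinomial naive Bayes on comment
  bags-of-words with stratified cross-validation; too-rare classes
  surface as a typed stratification error rather than a silent wrong
  answer.
* **Synthetic corpora with planted truth.** A generator emulating the
  study design (14 shifts/student, Beta completion propensities,
  completion-linked grades, category word pools with planted pairwise
  overlap, Zipf word frequencies) so the whole pipeline is testable
  end-to-end without any data download.

## Worked example

```python
import warnings
from reflexlens import ReflectionAnalysis
from reflexlens.synthetic import SyntheticConfig, generate_corpus

corpus, truth = generate_corpus(
    SyntheticConfig(n_students=116, target_corr=0.32, seed=1)
)
results = ReflectionAnalysis(corpus, jaccard_k=30, bootstrap=1000, seed=1).fit()
print(results.summary())
```

prints

```
Reflective-comment corpus analysis
==========================================================
students:   116    shifts:   1624    completed comments: 1086
completion rate: 0.669

Grade association (n = 116 students)
----------------------------------------------------------
  completion fraction vs grade: r = +0.2831  (t = 3.151, p = 0.002078)
  mean comment length vs grade: r = +0.2684  (t = 2.975, p = 0.003579)
  completer split at fraction > 0.5:
    completers     n = 82, median grade 77.126 (IQR 6.430)
    non-completers n = 34, median grade 74.375 (IQR 6.996)
    KS test: D = 0.2812, p = 0.03591

Pairwise vocabulary Jaccard (k = 30, B = 1000)
----------------------------------------------------------
  Interpreter-Reporter    J = 0.5385   p_left = 0.000999
      Manager-Reporter    J = 0.4286   p_left = 0.000999
     Educator-Reporter    J = 0.2500   p_left = 0.000999
  Interpreter-Manager     J = 0.3953   p_left = 0.000999
     Educator-Interpreter J = 0.2500   p_left = 0.000999
     Educator-Manager     J = 0.2766   p_left = 0.000999

Rating classifier
----------------------------------------------------------
  5-fold CV accuracy = 0.877 (alpha = 1, classes: Educator, Interpreter, Manager, Reporter)
```

Reading it: this synthetic cohort of 116 students planted a 0.32
population correlation between completion fraction and grade; the
pipeline estimates r = 0.28 (sampling noise at n = 116), completers'
median grade sits ~2.8 points above non-completers', and the KS test
separates the two grade distributions. The planted category pools
share 25% of their words pairwise, so every pair's top-30 vocabulary
similarity is far *below* what comment exchange would produce — all
left-tail p-values at the 1/(B+1) floor. `results.to_report()` /
`results.save(path)` export everything as one JSON document;
`results.plot_grade_scatter()` and `results.plot_grade_boxplot()`
draw the standard figures.

The same analysis from a shell:

```bash
reflexlens run --corpus shifts.csv --jaccard-k 30 --bootstrap 1000 \
    --seed 1 --out out/
reflexlens simulate --fixture tiny --out sim/   # synthetic corpus as CSV
```

The corpus CSV has one row per shift with columns
`student_id, shift_index, comment, rating, final_grade` (JSONL with the
same fields also works); stopword files are plain text, one word per
line, defaulting to the bundled English list.

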