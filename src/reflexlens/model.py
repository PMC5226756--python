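"""Model/Results objects orchestrating the full corpus analysis.

``ReflectionAnalysis`` is built from a corpus (plus stoplist and stage
parameters); ``fit()`` runs preprocessing, n-gram profiling, the
pairwise Jaccard resampling tests, the grade-association statistics and
the rating classifier, and returns a ``ReflectionResults`` carrying all
estimates with a ``summary()`` table, export helpers and plots.

The classifier stage is allowed to fail softly: when a rating category
is rarer than the number of folds (too little data to stratify), the
results record the typed reason and the rest of the analysis stands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__ as _version
from .corpus import Corpus, RIME_ORDER, read_corpus, write_report
from .errors import EmptyCategoryError, StratificationError
from .classify import CvReport, cv_evaluate
from .grades import AssociationReport, associate, effort_table
from .ngrams import (
    DEFAULT_TOP_K_BIGRAMS,
    DEFAULT_TOP_K_UNIGRAMS,
    VocabSet,
    category_vocabulary,
    count_ngrams,
    top_k,
)
from .preprocess import StopList, default_stoplist, preprocess_comment
from .similarity import JaccardResult, pairwise_jaccard_matrix

__all__ = ["ReflectionAnalysis", "ReflectionResults"]


class ReflectionAnalysis:
    """Reflective-comment analysis of one clerkship corpus.

    Parameters
    ----------
    corpus
        The corpus to analyse.
    stoplist
        Stopword list; defaults to the bundled English list.
    top_k_unigrams, top_k_bigrams
        Sizes of the headline most-common tables (50 words and 9
        two-word phrases by default).
    jaccard_k
        Vocabulary size for the per-category top-k sets the Jaccard
        tests compare.  Required thinking: similarity values depend on
        it, so it is always recorded in the results.
    bootstrap
        Number of label-exchange resamples B for each pairwise test.
    split_threshold
        Completion fraction above which (strictly) a student counts as
        a completer.
    folds, alpha
        Cross-validation folds and additive smoothing for the rating
        classifier.
    seed
        Master seed for every random stage.
    backend
        Word normaliser: "lemma" (inflectional rules) or "porter".
    """

    def __init__(
        self,
        corpus: Corpus,
        stoplist: StopList | None = None,
        *,
        top_k_unigrams: int = DEFAULT_TOP_K_UNIGRAMS,
        top_k_bigrams: int = DEFAULT_TOP_K_BIGRAMS,
        jaccard_k: int = 50,
        bootstrap: int = 1000,
        split_threshold: float = 0.5,
        folds: int = 5,
        alpha: float = 1.0,
        seed: int = 0,
        backend: str = "lemma",
        categories: tuple[str, ...] = RIME_ORDER,
    ):
        self.corpus = corpus
        self.stoplist = stoplist if stoplist is not None else default_stoplist()
        self.top_k_unigrams = top_k_unigrams
        self.top_k_bigrams = top_k_bigrams
        self.jaccard_k = jaccard_k
        self.bootstrap = bootstrap
        self.split_threshold = split_threshold
        self.folds = folds
        self.alpha = alpha
        self.seed = seed
        self.backend = backend
        self.categories = tuple(categories)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ReflectionAnalysis":
        return cls(read_corpus(path), **kwargs)

    def fit(self) -> "ReflectionResults":
        processed = [
            preprocess_comment(shift.raw_text, self.stoplist, backend=self.backend)
            for _, shift in self.corpus.iter_shifts()
        ]
        n_shifts = len(processed)
        n_complete = sum(pc.complete for pc in processed)

        uni = count_ngrams(processed, 1)
        bi = count_ngrams(processed, 2)
        top_uni = top_k(uni, self.top_k_unigrams)
        top_bi = top_k(bi, self.top_k_bigrams)

        vocabularies: dict[str, VocabSet] = {}
        for cat in self.categories:
            try:
                vocabularies[cat] = category_vocabulary(
                    self.corpus, cat, self.jaccard_k, self.stoplist, backend=self.backend
                )
            except EmptyCategoryError as exc:
                warnings.warn(f"category vocabulary skipped: {exc}", stacklevel=2)

        usable_cats = [c for c in self.categories if c in vocabularies]
        jaccard_results: list[JaccardResult] = []
        if len(usable_cats) >= 2:
            jaccard_results = pairwise_jaccard_matrix(
                self.corpus, usable_cats, self.jaccard_k, self.bootstrap,
                self.seed, self.stoplist, backend=self.backend,
            )

        association = associate(
            self.corpus, self.stoplist,
            threshold=self.split_threshold, backend=self.backend,
        )

        classifier: CvReport | None = None
        classifier_skip_reason: str | None = None
        try:
            classifier = cv_evaluate(
                self.corpus, self.folds, self.seed, self.alpha, self.stoplist,
                backend=self.backend,
            )
        except (StratificationError, ValueError) as exc:
            classifier_skip_reason = str(exc)
            warnings.warn(f"classifier stage skipped: {exc}", stacklevel=2)

        return ReflectionResults(
            model=self,
            n_shifts=n_shifts,
            n_complete=n_complete,
            unigram_counts={" ".join(g): c for g, c in uni.counts.items()},
            bigram_counts={" ".join(g): c for g, c in bi.counts.items()},
            top_unigrams=[" ".join(g) for g in top_uni],
            top_bigrams=[" ".join(g) for g in top_bi],
            vocabularies=vocabularies,
            jaccard=jaccard_results,
            association=association,
            classifier=classifier,
            classifier_skip_reason=classifier_skip_reason,
        )


@dataclass
class ReflectionResults:
    """Fitted estimates of a :class:`ReflectionAnalysis`."""

    model: ReflectionAnalysis
    n_shifts: int
    n_complete: int
    unigram_counts: dict[str, int]
    bigram_counts: dict[str, int]
    top_unigrams: list[str]
    top_bigrams: list[str]
    vocabularies: dict[str, VocabSet]
    jaccard: list[JaccardResult]
    association: AssociationReport
    classifier: CvReport | None
    classifier_skip_reason: str | None = None
    _effort_table: object = field(default=None, repr=False)

    @property
    def efforts(self):
        """Per-student effort/grade table (cached DataFrame)."""
        if self._effort_table is None:
            self._effort_table = effort_table(
                self.model.corpus, self.model.stoplist, backend=self.model.backend
            )
        return self._effort_table

    def to_report(self) -> dict:
        a = self.association
        return {
            "preprocessing_summary": {
                "n_students": self.model.corpus.n_students,
                "n_shifts": self.n_shifts,
                "n_complete": self.n_complete,
                "completion_rate": self.n_complete / self.n_shifts if self.n_shifts else 0.0,
                "stoplist_size": len(self.model.stoplist),
                "stoplist_sources": list(self.model.stoplist.source_files),
                "backend": self.model.backend,
            },
            "ngram_tables": {
                "top_unigrams": [
                    [g, self.unigram_counts[g]] for g in self.top_unigrams
                ],
                "top_bigrams": [
                    [g, self.bigram_counts[g]] for g in self.top_bigrams
                ],
                "category_vocabularies": {
                    cat: {
                        "k": v.k,
                        "lemmas": sorted(v.lemmas),
                        "tie_note": v.tie_note,
                    }
                    for cat, v in self.vocabularies.items()
                },
            },
            "jaccard_matrix": [r.to_dict() for r in self.jaccard],
            "grade_association": a.to_dict(),
            "classifier": (
                self.classifier.to_dict()
                if self.classifier is not None
                else {"skipped": True, "reason": self.classifier_skip_reason}
            ),
            "config": {
                "version": _version,
                "seed": self.model.seed,
                "jaccard_k": self.model.jaccard_k,
                "bootstrap": self.model.bootstrap,
                "top_k_unigrams": self.model.top_k_unigrams,
                "top_k_bigrams": self.model.top_k_bigrams,
                "split_threshold": self.model.split_threshold,
                "folds": self.model.folds,
                "alpha": self.model.alpha,
                "backend": self.model.backend,
            },
        }

    def save(self, path: str | Path) -> None:
        """Write the JSON report via the corpus I/O layer."""
        write_report(self.to_report(), path)

    def summary(self) -> str:
        """Human-readable table of the headline estimates."""
        a = self.association
        lines = [
            "Reflective-comment corpus analysis",
            "=" * 58,
            f"students: {self.model.corpus.n_students:>5}    shifts: {self.n_shifts:>6}"
            f"    completed comments: {self.n_complete}",
            f"completion rate: {self.n_complete / self.n_shifts:.3f}"
            if self.n_shifts else "completion rate: n/a",
            "",
            "Grade association (n = %d students)" % a.n,
            "-" * 58,
            f"  completion fraction vs grade: r = {a.r_completion:+.4f}"
            f"  (t = {a.t_completion:.3f}, p = {a.p_completion:.4g})",
            f"  mean comment length vs grade: r = {a.r_length:+.4f}"
            f"  (t = {a.t_length:.3f}, p = {a.p_length:.4g})",
            f"  completer split at fraction > {a.threshold:g}:",
            f"    completers     n = {a.completers.n}, median grade {a.completers.median:.3f}"
            f" (IQR {a.completers.iqr:.3f})",
        ]
        if a.noncompleters is not None:
            lines.append(
                f"    non-completers n = {a.noncompleters.n}, median grade "
                f"{a.noncompleters.median:.3f} (IQR {a.noncompleters.iqr:.3f})"
            )
        if a.ks_D is not None:
            lines.append(f"    KS test: D = {a.ks_D:.4f}, p = {a.ks_p:.4g}")
        if self.jaccard:
            lines += ["", f"Pairwise vocabulary Jaccard (k = {self.model.jaccard_k}, "
                          f"B = {self.model.bootstrap})", "-" * 58]
            for r in self.jaccard:
                lines.append(
                    f"  {r.pair[0]:>11}-{r.pair[1]:<11} J = {r.J_obs:.4f}"
                    f"   p_left = {r.p_left:.4g}"
                )
        lines += ["", "Rating classifier", "-" * 58]
        if self.classifier is not None:
            c = self.classifier
            lines.append(
                f"  {c.folds}-fold CV accuracy = {c.mean_accuracy:.3f} "
                f"(alpha = {c.alpha:g}, classes: {', '.join(c.classes)})"
            )
        else:
            lines.append(f"  skipped: {self.classifier_skip_reason}")
        return "\n".join(lines)

    # ----- plots -------------------------------------------------------
    def plot_grade_scatter(self, ax=None):
        """Scatter of grade vs completion fraction with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.efforts
        comp = df["completion_fraction"] > self.model.split_threshold
        ax.scatter(df.loc[~comp, "completion_fraction"], df.loc[~comp, "final_grade"],
                   c="black", label="non-completers")
        ax.scatter(df.loc[comp, "completion_fraction"], df.loc[comp, "final_grade"],
                   facecolors="none", edgecolors="black", label="completers")
        fit = self.association.fit_completion
        xs = [df["completion_fraction"].min(), df["completion_fraction"].max()]
        ax.plot(xs, [fit.intercept + fit.slope * x for x in xs], "k--")
        ax.set_xlabel("completion fraction")
        ax.set_ylabel("final grade")
        ax.legend()
        return ax

    def plot_grade_boxplot(self, ax=None):
        """Notched boxplots of grades for completers vs non-completers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.efforts
        comp = df["completion_fraction"] > self.model.split_threshold
        groups = [df.loc[comp, "final_grade"], df.loc[~comp, "final_grade"]]
        ax.boxplot(
            [g for g in groups if len(g)],
            notch=True, whis=(2, 97),
            tick_labels=[l for g, l in zip(groups, ["completers", "non-completers"])
                         if len(g)],
        )
        ax.set_ylabel("final grade")
        return ax
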