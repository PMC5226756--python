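"""Unigram/bigram frequency tables and per-category top-k vocabularies.

Bigrams are pairs of *adjacent* content lemmas within a single comment;
they never span comment boundaries.  Per-category vocabularies pool the
completed comments rated with exactly one base category: hybrid ratings
(two circled rungs) are excluded because the evaluator's intent is
ambiguous, and "Inadequate" is excluded by default because such ratings
are typically too few to characterise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .corpus import Corpus, RIME_ORDER
from .errors import EmptyCategoryError
from .preprocess import ProcessedComment, StopList, preprocess_comment

__all__ = [
    "FrequencyTable",
    "VocabSet",
    "count_ngrams",
    "top_k",
    "category_vocabulary",
    "category_comments",
    "DEFAULT_TOP_K_UNIGRAMS",
    "DEFAULT_TOP_K_BIGRAMS",
]

#: Table sizes used for the headline "most common words/phrases" report.
DEFAULT_TOP_K_UNIGRAMS = 50
DEFAULT_TOP_K_BIGRAMS = 9


@dataclass
class FrequencyTable:
    n: int
    counts: dict[tuple[str, ...], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | Path) -> None:
        """Export as ``ngram <tab> count``, descending, ties lexicographic."""
        lines = [
            f"{' '.join(gram)}\t{count}"
            for gram, count in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


@dataclass
class VocabSet:
    """Top-k unigram vocabulary of one rating category."""

    category: str
    k: int
    lemmas: frozenset[str]
    tie_note: str = ""


def count_ngrams(comments: list[ProcessedComment], n: int) -> FrequencyTable:
    """Count n-grams (n in {1, 2}) over the content lemmas of completed
    comments; incomplete comments contribute nothing."""
    if n not in (1, 2):
        raise ValueError(f"n-gram order must be 1 or 2, got {n}")
    counts: Counter[tuple[str, ...]] = Counter()
    for comment in comments:
        if not comment.complete:
            continue
        lemmas = comment.content_lemmas
        if n == 1:
            counts.update((l,) for l in lemmas)
        else:
            counts.update(zip(lemmas, lemmas[1:]))
    return FrequencyTable(n=n, counts=dict(counts))


def top_k(table: FrequencyTable, k: int) -> list[tuple[str, ...]]:
    """The k most frequent n-grams, descending by count, ties broken
    lexicographically so the ranking is deterministic."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [gram for gram, _ in ranked[:k]]


def _tie_note(table: FrequencyTable, k: int) -> str:
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if k == 0 or len(ranked) <= k:
        return ""
    boundary = ranked[k - 1][1]
    tied = [" ".join(g) for g, c in ranked if c == boundary]
    if len(tied) > 1 and ranked[k][1] == boundary:
        return (
            f"count {boundary} ties at rank {k} broken lexicographically among: "
            + ", ".join(sorted(tied))
        )
    return ""


def category_comments(
    corpus: Corpus,
    category: str,
    stoplist: StopList,
    *,
    backend: str = "lemma",
) -> list[ProcessedComment]:
    """Completed comments whose shift rating is exactly ``category``
    (single-category ratings only; hybrids excluded)."""
    out = []
    for _, shift in corpus.iter_shifts():
        if shift.rating is None or shift.rating.hybrid:
            continue
        if shift.rating.categories[0] != category:
            continue
        pc = preprocess_comment(shift.raw_text, stoplist, backend=backend)
        if pc.complete:
            out.append(pc)
    return out


def category_vocabulary(
    corpus: Corpus,
    category: str,
    k: int,
    stoplist: StopList,
    *,
    backend: str = "lemma",
) -> VocabSet:
    """Top-k unigram vocabulary of one base rating category.

    Raises :class:`EmptyCategoryError` when the category has no eligible
    completed comments (e.g. a corpus rated only with hybrids).
    """
    if category not in RIME_ORDER + ("Inadequate",):
        raise ValueError(f"unknown base category {category!r}")
    comments = category_comments(corpus, category, stoplist, backend=backend)
    if not comments:
        raise EmptyCategoryError(category)
    table = count_ngrams(comments, 1)
    lemmas = frozenset(g[0] for g in top_k(table, k))
    return VocabSet(category=category, k=k, lemmas=lemmas, tie_note=_tie_note(table, k))
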