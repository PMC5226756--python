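"""Jaccard similarity between category vocabularies, with a resampling null.

The observed statistic is J = |A ∩ B| / |A ∪ B| between the top-k
unigram vocabularies of two rating categories.  Its significance comes
from label exchange: pool the two categories' eligible comments,
repeatedly reassign comments to two groups of the original sizes
without replacement, and recompute the two top-k vocabularies and their
Jaccard each time.  The resampling unit is the whole comment, which
respects the dependence between words written in the same comment.

The reported p-value is left-tailed,

    p_left = (1 + #{J_null <= J_obs}) / (B + 1),

so a small p means the two categories' vocabularies are more *distinct*
than label exchange predicts.  The +1 correction makes it a valid
permutation p-value and bounds it away from zero at 1/(B+1).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .corpus import Corpus
from .errors import EmptyCategoryError
from .ngrams import category_comments
from .preprocess import ProcessedComment, StopList

__all__ = [
    "JaccardResult",
    "jaccard",
    "jaccard_test",
    "pairwise_jaccard_matrix",
    "holm_adjust",
    "results_to_tsv",
]

DEFAULT_BOOTSTRAP = 1000


def jaccard(a: set, b: set) -> float:
    """|A ∩ B| / |A ∪ B|.  Undefined (raises) when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard similarity is undefined for two empty sets")
    return len(a & b) / len(union)


@dataclass
class JaccardResult:
    pair: tuple[str, str]
    J_obs: float
    k: int
    B: int
    null_J: np.ndarray
    p_left: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "J_obs": self.J_obs,
            "k": self.k,
            "B": self.B,
            "p_left": self.p_left,
            "seed": self.seed,
        }


def _count_matrix(comments: list[ProcessedComment]) -> tuple[np.ndarray, list[str]]:
    """Comment-by-lemma count matrix with columns sorted lexicographically,
    so a stable descending-count argsort breaks ties lexicographically."""
    vocab = sorted({l for c in comments for l in c.content_lemmas})
    index = {w: j for j, w in enumerate(vocab)}
    mat = np.zeros((len(comments), len(vocab)), dtype=np.int64)
    for i, c in enumerate(comments):
        for l in c.content_lemmas:
            mat[i, index[l]] += 1
    return mat, vocab


def _topk_ids(counts: np.ndarray, k: int) -> np.ndarray:
    """Column ids of the top-k positive counts, ties lexicographic
    (columns are pre-sorted, argsort is stable)."""
    order = np.argsort(-counts, kind="stable")
    nonzero = int((counts > 0).sum())
    return order[: min(k, nonzero)]


def jaccard_test(
    corpus: Corpus,
    cat_a: str,
    cat_b: str,
    k: int,
    B: int,
    seed: int,
    stoplist: StopList,
    *,
    backend: str = "lemma",
) -> JaccardResult:
    """Observed top-k vocabulary Jaccard between two categories and its
    left-tail p-value under comment-level label exchange.

    ``k`` is required: the statistic depends on the vocabulary size and
    defaulting it silently would make reported similarities ambiguous.
    """
    if B < 1:
        raise ValueError(f"number of resamples B must be >= 1, got {B}")
    if k < 1:
        raise ValueError(f"vocabulary size k must be >= 1, got {k}")
    comments_a = category_comments(corpus, cat_a, stoplist, backend=backend)
    comments_b = category_comments(corpus, cat_b, stoplist, backend=backend)
    if not comments_a:
        raise EmptyCategoryError(cat_a)
    if not comments_b:
        raise EmptyCategoryError(cat_b)

    pooled = comments_a + comments_b
    n_a = len(comments_a)
    mat, _vocab = _count_matrix(pooled)
    counts_a = mat[:n_a].sum(axis=0)
    counts_b = mat[n_a:].sum(axis=0)
    obs_a = frozenset(_topk_ids(counts_a, k).tolist())
    obs_b = frozenset(_topk_ids(counts_b, k).tolist())
    j_obs = jaccard(obs_a, obs_b)

    rng = np.random.default_rng(seed)
    n = len(pooled)
    null = np.empty(B, dtype=float)
    for b in range(B):
        perm = rng.permutation(n)
        ca = mat[perm[:n_a]].sum(axis=0)
        cb = mat[perm[n_a:]].sum(axis=0)
        sa = frozenset(_topk_ids(ca, k).tolist())
        sb = frozenset(_topk_ids(cb, k).tolist())
        null[b] = jaccard(sa, sb)
    p_left = (1 + int((null <= j_obs).sum())) / (B + 1)
    return JaccardResult(
        pair=(cat_a, cat_b), J_obs=j_obs, k=k, B=B, null_J=null, p_left=p_left, seed=seed
    )


def _pair_seed(master_seed: int, cat_a: str, cat_b: str) -> int:
    """Per-pair child seed derived from the sorted pair names, so the
    matrix is invariant to category order."""
    tag = "|".join(sorted((cat_a, cat_b)))
    return (int(master_seed) ^ zlib.crc32(tag.encode("utf-8"))) & 0x7FFFFFFF


def pairwise_jaccard_matrix(
    corpus: Corpus,
    categories: list[str],
    k: int,
    B: int,
    seed: int,
    stoplist: StopList,
    *,
    backend: str = "lemma",
    holm: bool = False,
) -> list[JaccardResult]:
    """One :class:`JaccardResult` per unordered category pair.

    With ``holm=True`` each result gains a ``p_holm`` attribute (Holm
    step-down adjustment of the per-pair p-values); by default raw
    per-pair p-values are reported.
    """
    if len(categories) < 2:
        raise ValueError("need at least two categories for a pairwise matrix")
    results = []
    for cat_a, cat_b in combinations(categories, 2):
        a, b = sorted((cat_a, cat_b))
        res = jaccard_test(
            corpus, a, b, k, B, _pair_seed(seed, a, b), stoplist, backend=backend
        )
        results.append(res)
    if holm:
        adjusted = holm_adjust([r.p_left for r in results])
        for r, p in zip(results, adjusted):
            r.p_holm = p
    return results


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjustment (family-wise error control)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def results_to_tsv(results: list[JaccardResult], path: str | Path) -> None:
    lines = ["pair\tJ_obs\tp_left\tB\tk\tseed"]
    for r in results:
        lines.append(
            f"{r.pair[0]}-{r.pair[1]}\t{r.J_obs:.6g}\t{r.p_left:.6g}\t{r.B}\t{r.k}\t{r.seed}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
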