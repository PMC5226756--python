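"""Multinomial naive Bayes over comment bags-of-words.

Predicts the attending's RIME rating from the content lemmas of a
completed comment.  Training mirrors the category analyses: only
completed comments with a single-category rating are used (hybrids and
"Inadequate" excluded), counts are additively smoothed with ``alpha``
(Laplace by default).  Stratified k-fold cross-validation surfaces the
"insufficient data" condition as a typed :class:`StratificationError`
whenever any class is rarer than the number of folds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB

from .corpus import Corpus, RIME_ORDER
from .errors import StratificationError
from .ngrams import category_comments
from .preprocess import ProcessedComment, StopList

__all__ = ["BowModel", "train_nb", "predict_log_posterior", "cv_evaluate", "CvReport"]


@dataclass
class BowModel:
    classes: list[str]
    vocabulary: list[str]
    log_priors: np.ndarray          # (n_classes,)
    log_likelihoods: np.ndarray     # (n_classes, n_vocab), smoothed
    alpha: float


def _bow_matrix(
    comments: list[ProcessedComment], vocabulary: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    if vocabulary is None:
        vocabulary = sorted({l for c in comments for l in c.content_lemmas})
    index = {w: j for j, w in enumerate(vocabulary)}
    mat = np.zeros((len(comments), len(vocabulary)), dtype=np.float64)
    for i, c in enumerate(comments):
        for lemma in c.content_lemmas:
            j = index.get(lemma)
            if j is not None:  # out-of-vocabulary lemmas are dropped
                mat[i, j] += 1
    return mat, vocabulary


def train_nb(
    comments: list[ProcessedComment], labels: list[str], alpha: float = 1.0
) -> BowModel:
    """Fit a multinomial naive-Bayes model on labelled completed comments."""
    if alpha <= 0:
        raise ValueError(f"smoothing alpha must be > 0, got {alpha}")
    if len(comments) != len(labels):
        raise ValueError("comments and labels are not aligned")
    usable = [(c, l) for c, l in zip(comments, labels) if c.complete]
    if not usable:
        raise ValueError("no completed comments to train on (empty vocabulary)")
    comments, labels = map(list, zip(*usable))
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    mat, vocabulary = _bow_matrix(comments)
    if not vocabulary:
        raise ValueError("empty vocabulary: no content lemmas in training comments")
    clf = MultinomialNB(alpha=alpha)
    clf.fit(mat, labels)
    return BowModel(
        classes=list(clf.classes_),
        vocabulary=vocabulary,
        log_priors=clf.class_log_prior_.copy(),
        log_likelihoods=clf.feature_log_prob_.copy(),
        alpha=alpha,
    )


def predict_log_posterior(model: BowModel, comment: ProcessedComment) -> dict[str, float]:
    """Normalised log posterior over classes for one comment.

    Lemmas outside the training vocabulary are ignored (they carry no
    information under the fitted likelihoods).
    """
    x, _ = _bow_matrix([comment], model.vocabulary)
    joint = model.log_priors + x @ model.log_likelihoods.T
    joint = joint.ravel()
    norm = joint - _logsumexp(joint)
    return dict(zip(model.classes, norm.tolist()))


def _logsumexp(v: np.ndarray) -> float:
    m = np.max(v)
    return float(m + np.log(np.sum(np.exp(v - m))))


@dataclass
class CvReport:
    folds: int
    alpha: float
    seed: int
    classes: list[str]
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: np.ndarray  # rows true, cols predicted, class order as in `classes`

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "alpha": self.alpha,
            "seed": self.seed,
            "classes": self.classes,
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "confusion": self.confusion.tolist(),
        }

    def confusion_to_tsv(self, path) -> None:
        from pathlib import Path

        lines = ["true\\pred\t" + "\t".join(self.classes)]
        for cls, row in zip(self.classes, self.confusion):
            lines.append(cls + "\t" + "\t".join(str(int(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def cv_evaluate(
    corpus: Corpus,
    folds: int,
    seed: int,
    alpha: float = 1.0,
    stoplist: StopList | None = None,
    *,
    backend: str = "lemma",
) -> CvReport:
    """Stratified k-fold cross-validated accuracy of the rating classifier.

    Raises :class:`StratificationError` naming the offending class when
    any class has fewer completed comments than folds — the typed form
    of having too little data to train the classifier.
    """
    if folds < 2:
        raise ValueError(f"need at least 2 folds, got {folds}")
    if stoplist is None:
        from .preprocess import default_stoplist

        stoplist = default_stoplist()
    comments: list[ProcessedComment] = []
    labels: list[str] = []
    for category in RIME_ORDER:
        for pc in category_comments(corpus, category, stoplist, backend=backend):
            comments.append(pc)
            labels.append(category)
    class_counts = Counter(labels)
    for category in sorted(class_counts):
        if class_counts[category] < folds:
            raise StratificationError(category, class_counts[category], folds)
    if len(class_counts) < 2:
        raise ValueError("need at least 2 classes with completed comments")

    classes = sorted(class_counts)
    cls_index = {c: i for i, c in enumerate(classes)}
    y = np.array(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = []
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    dummy_X = np.zeros(len(comments))
    for train_idx, test_idx in skf.split(dummy_X, y):
        model = train_nb(
            [comments[i] for i in train_idx], [labels[i] for i in train_idx], alpha=alpha
        )
        correct = 0
        for i in test_idx:
            post = predict_log_posterior(model, comments[i])
            pred = max(sorted(post), key=lambda c: post[c])
            confusion[cls_index[labels[i]], cls_index[pred]] += 1
            if pred == labels[i]:
                correct += 1
        fold_acc.append(correct / len(test_idx))
    return CvReport(
        folds=folds,
        alpha=alpha,
        seed=seed,
        classes=classes,
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        confusion=confusion,
    )
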