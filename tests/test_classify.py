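import dataclasses
import math

import numpy as np
import pytest

from reflexlens.classify import cv_evaluate, predict_log_posterior, train_nb
from reflexlens.errors import StratificationError
from reflexlens.preprocess import ProcessedComment
from reflexlens.synthetic import fixture_config, generate_corpus


def pc(*lemmas):
    return ProcessedComment(raw_text=" ".join(lemmas), tokens=list(lemmas),
                            content_lemmas=list(lemmas), complete=bool(lemmas))


class TestTrainNB:
    def test_disjoint_words_classified_to_own_class(self):
        model = train_nb([pc("alpha"), pc("beta")], ["A", "B"], alpha=1.0)
        post_a = predict_log_posterior(model, pc("alpha"))
        post_b = predict_log_posterior(model, pc("beta"))
        assert post_a["A"] > post_a["B"]
        assert post_b["B"] > post_b["A"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_nb([pc("a"), pc("b")], ["X", "X"])

    def test_all_incomplete_rejected(self):
        empty = ProcessedComment(raw_text="", tokens=[], content_lemmas=[], complete=False)
        with pytest.raises(ValueError):
            train_nb([empty, empty], ["A", "B"])

    @pytest.mark.parametrize("alpha", [0.0, -1.0])
    def test_alpha_validation(self, alpha):
        with pytest.raises(ValueError):
            train_nb([pc("a"), pc("b")], ["A", "B"], alpha=alpha)

    def test_hand_computed_posterior(self):
        """4-comment fixture checked against smoothed-count arithmetic
        done by hand (alpha = 1, vocabulary {a, b, c})."""
        comments = [pc("a", "a", "b"), pc("a"), pc("b", "c"), pc("c")]
        labels = ["X", "X", "Y", "Y"]
        model = train_nb(comments, labels, alpha=1.0)
        # class X: counts a=3, b=1, c=0 over 4 tokens -> (4/7, 2/7, 1/7)
        # class Y: counts a=0, b=1, c=2 over 3 tokens -> (1/6, 2/6, 3/6)
        lik = np.exp(model.log_likelihoods)
        x_row = lik[model.classes.index("X")]
        y_row = lik[model.classes.index("Y")]
        vocab_idx = {w: i for i, w in enumerate(model.vocabulary)}
        assert x_row[vocab_idx["a"]] == pytest.approx(4 / 7)
        assert x_row[vocab_idx["b"]] == pytest.approx(2 / 7)
        assert x_row[vocab_idx["c"]] == pytest.approx(1 / 7)
        assert y_row[vocab_idx["a"]] == pytest.approx(1 / 6)
        # posterior of test comment "a b": joint X = 1/2 * 4/7 * 2/7,
        # joint Y = 1/2 * 1/6 * 2/6; normalised by hand:
        jx = 0.5 * (4 / 7) * (2 / 7)
        jy = 0.5 * (1 / 6) * (2 / 6)
        post = predict_log_posterior(model, pc("a", "b"))
        assert math.exp(post["X"]) == pytest.approx(jx / (jx + jy), abs=1e-12)

    def test_likelihoods_and_priors_normalised(self):
        model = train_nb([pc("a", "b"), pc("c"), pc("a")], ["X", "Y", "X"])
        assert np.exp(model.log_priors).sum() == pytest.approx(1.0)
        assert np.allclose(np.exp(model.log_likelihoods).sum(axis=1), 1.0)

    def test_posterior_stable_under_corpus_duplication(self):
        """Duplicating the training corpus leaves predicted labels (and,
        up to smoothing attenuation, posteriors) unchanged."""
        comments = [pc("a", "a", "b"), pc("a"), pc("b", "c"), pc("c")] * 20
        labels = ["X", "X", "Y", "Y"] * 20
        m1 = train_nb(comments, labels, alpha=1.0)
        m2 = train_nb(comments * 2, labels * 2, alpha=1.0)
        test = pc("a", "b")
        p1 = predict_log_posterior(m1, test)
        p2 = predict_log_posterior(m2, test)
        assert max(p1, key=p1.get) == max(p2, key=p2.get)
        # fixed-alpha smoothing attenuates with corpus size, so the
        # posteriors converge rather than match exactly
        assert math.exp(p1["X"]) == pytest.approx(math.exp(p2["X"]), abs=0.02)
        # exact invariance holds when alpha scales with the corpus
        m3 = train_nb(comments * 2, labels * 2, alpha=2.0)
        p3 = predict_log_posterior(m3, test)
        assert p3["X"] == pytest.approx(p1["X"], abs=1e-12)

    def test_oov_lemmas_ignored_at_prediction(self):
        model = train_nb([pc("a"), pc("b")], ["A", "B"])
        with_oov = predict_log_posterior(model, pc("a", "zzz"))
        without = predict_log_posterior(model, pc("a"))
        assert with_oov == pytest.approx(without)


@pytest.fixture(scope="module")
def small_separable():
    config = dataclasses.replace(fixture_config("separable"), n_students=80, seed=31)
    return generate_corpus(config)[0]


class TestCvEvaluate:
    def test_separable_accuracy_high(self, small_separable, stoplist):
        report = cv_evaluate(small_separable, folds=5, seed=2, alpha=1.0,
                             stoplist=stoplist)
        assert report.mean_accuracy >= 0.9
        assert len(report.fold_accuracies) == 5
        assert report.confusion.sum() == sum(
            int(report.confusion[i].sum()) for i in range(len(report.classes))
        )

    def test_deterministic_given_seed(self, small_separable, stoplist):
        r1 = cv_evaluate(small_separable, folds=4, seed=9, stoplist=stoplist)
        r2 = cv_evaluate(small_separable, folds=4, seed=9, stoplist=stoplist)
        assert r1.fold_accuracies == r2.fold_accuracies
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_rare_class_raises_stratification_error(self, stoplist):
        # Reporter given vanishing probability -> fewer members than folds
        config = dataclasses.replace(
            fixture_config("separable"), n_students=6, seed=5,
            category_probs={"Inadequate": 0.0, "Reporter": 0.01,
                            "Interpreter": 0.33, "Manager": 0.33, "Educator": 0.33},
        )
        corpus, _ = generate_corpus(config)
        with pytest.raises(StratificationError):
            cv_evaluate(corpus, folds=30, seed=1, stoplist=stoplist)

    def test_folds_validation(self, small_separable, stoplist):
        with pytest.raises(ValueError):
            cv_evaluate(small_separable, folds=1, seed=1, stoplist=stoplist)

    def test_accuracy_monotone_in_vocabulary_divergence(self, stoplist):
        """3-point check: mean CV accuracy does not decrease as planted
        category vocabularies diverge (identical -> partial -> disjoint)."""
        accs = []
        for rho in (1.0, 0.3, 0.0):
            config = dataclasses.replace(
                fixture_config("separable"), n_students=60, rho_v=rho, seed=17,
            )
            corpus, _ = generate_corpus(config)
            accs.append(
                cv_evaluate(corpus, folds=4, seed=3, stoplist=stoplist).mean_accuracy
            )
        assert accs[0] <= accs[1] + 0.05 <= accs[2] + 0.10
        assert accs[2] > accs[0]
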