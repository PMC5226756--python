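import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reflexlens.corpus import ShiftRecord, Student
from reflexlens.errors import DegenerateInputError
from reflexlens.grades import (
    StudentEffort,
    associate,
    corr_t_test,
    group_summary,
    ks_2sample,
    pearson_r,
    split_by_completion,
    student_effort,
)
from reflexlens.preprocess import StopList

EMPTY_STOP = StopList(words=frozenset())
FLOATS = st.floats(min_value=-100, max_value=100, allow_nan=False)


def make_student(texts, grade=80.0):
    return Student(
        student_id="s",
        final_grade=grade,
        shifts=[ShiftRecord(shift_index=i + 1, raw_text=t) for i, t in enumerate(texts)],
    )


def brute_force_ks(a, b):
    """Independent oracle: sweep the pooled points and take the largest
    ECDF gap."""
    best = 0.0
    for t in list(a) + list(b):
        fa = sum(1 for x in a if x <= t) / len(a)
        fb = sum(1 for x in b if x <= t) / len(b)
        best = max(best, abs(fa - fb))
    return best


class TestStudentEffort:
    def test_half_complete(self, stoplist):
        student = make_student(["word"] * 7 + [""] * 7)
        eff = student_effort(student, stoplist)
        assert eff.n_shifts == 14 and eff.n_complete == 7
        assert eff.completion_fraction == 0.5

    def test_all_empty(self, stoplist):
        eff = student_effort(make_student([""] * 5), stoplist)
        assert eff.completion_fraction == 0.0 and eff.mean_length == 0.0

    def test_mean_length_counts_raw_tokens(self, stoplist):
        # 10 raw words (stopwords included) then an empty shift -> mean 5
        student = make_student(["the quick brown fox jumps over the lazy dog again", ""])
        assert student_effort(student, stoplist).mean_length == 5.0

    def test_content_length_convention(self, stoplist):
        student = make_student(["the patient of it", ""])
        eff = student_effort(student, stoplist, length_convention="content")
        assert eff.mean_length == 0.5  # only "patient" survives

    def test_zero_shifts_rejected(self, stoplist):
        with pytest.raises(ValueError):
            student_effort(Student(student_id="s", final_grade=80.0, shifts=[]), stoplist)


class TestPearson:
    def test_perfect_line(self):
        fit = pearson_r([1, 2, 3, 4], [3, 5, 7, 9])  # y = 2x + 1
        assert fit.r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_orthogonal_after_centering(self):
        assert pearson_r([-1, 0, 1, 0], [0, 1, 0, -1]).r == pytest.approx(0.0, abs=1e-15)

    def test_fixed_five_points_hand_computation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 7.0]
        # hand arithmetic: r = cov / (sd_x sd_y)
        mx, my = sum(x) / 5, sum(y) / 5
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        vx = sum((a - mx) ** 2 for a in x)
        vy = sum((b - my) ** 2 for b in y)
        expected = cov / math.sqrt(vx * vy)
        assert pearson_r(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_few_points(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1, 2], [3, 4])

    @given(
        st.lists(st.tuples(FLOATS, FLOATS), min_size=4, max_size=20),
        st.floats(min_value=0.1, max_value=10),
        FLOATS,
    )
    @settings(max_examples=150, deadline=None)
    def test_affine_invariance(self, pts, scale, shift):
        x = [p[0] for p in pts]
        y = [p[1] for p in pts]
        transformed = [scale * v + shift for v in x]
        if np.ptp(x) == 0 or np.ptp(y) == 0 or np.ptp(transformed) == 0:
            return  # degenerate after rounding; out of scope here
        base = pearson_r(x, y).r
        rescaled = pearson_r(transformed, y).r
        assert rescaled == pytest.approx(base, abs=1e-9)


class TestCorrTTest:
    def test_null(self):
        assert corr_t_test(0.0, 30) == (0.0, 1.0)

    def test_closed_form(self):
        # t = 0.5 * sqrt(25) / sqrt(0.75)
        t, p = corr_t_test(0.5, 27)
        assert t == pytest.approx(0.5 * 5 / math.sqrt(0.75), abs=1e-4)
        assert t == pytest.approx(2.8868, abs=1e-4)
        assert 0 < p < 0.01

    def test_perfect_correlation_sentinel(self):
        t, p = corr_t_test(1.0, 10)
        assert math.isinf(t) and p == 0.0
        t_neg, _ = corr_t_test(-1.0, 10)
        assert t_neg == -math.inf

    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_small_n_rejected(self, n):
        with pytest.raises(ValueError):
            corr_t_test(0.3, n)

    def test_out_of_range_r(self):
        with pytest.raises(ValueError):
            corr_t_test(1.5, 10)


def eff(fraction):
    return StudentEffort(student_id="s", n_shifts=10, n_complete=int(10 * fraction),
                         completion_fraction=fraction, mean_length=1.0)


class TestSplit:
    def test_boundary_goes_to_noncompleters(self):
        comp, non = split_by_completion([eff(0.6), eff(0.5), eff(0.4)], [1, 2, 3])
        assert [e.completion_fraction for e, _ in comp] == [0.6]
        assert [e.completion_fraction for e, _ in non] == [0.5, 0.4]

    def test_all_completers_allowed(self):
        comp, non = split_by_completion([eff(0.9), eff(0.8)], [1, 2])
        assert len(comp) == 2 and non == []

    def test_threshold_zero(self):
        comp, non = split_by_completion([eff(0.1), eff(0.0)], [1, 2], threshold=0.0)
        assert len(comp) == 1 and len(non) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_by_completion([], [])


class TestKS:
    def test_identical_samples(self):
        D, p = ks_2sample([1, 2, 3], [1, 2, 3])
        assert D == 0.0

    def test_separated_supports(self):
        D, _ = ks_2sample([1, 2, 3], [10, 11, 12])
        assert D == 1.0

    def test_hand_case(self):
        D, _ = ks_2sample([1, 2], [1.5, 2.5])
        assert D == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_2sample([], [1.0])

    @given(
        st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False),
                 min_size=1, max_size=15),
        st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False),
                 min_size=1, max_size=15),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, a, b):
        D, _ = ks_2sample(a, b)
        assert D == pytest.approx(brute_force_ks(a, b), abs=1e-12)


class TestGroupSummary:
    def test_one_to_five(self):
        s = group_summary([1, 2, 3, 4, 5])
        assert s.median == 3.0
        assert s.iqr == 2.0  # linear-interpolation quantiles
        assert s.notch_ci[0] < 3.0 < s.notch_ci[1]

    def test_single_value_degenerate(self):
        s = group_summary([7.5])
        assert s.median == 7.5 and s.iqr == 0.0
        assert s.notch_ci == (7.5, 7.5)

    def test_notch_symmetric_about_median(self):
        s = group_summary([10, 20, 30, 40, 50, 60])
        lo, hi = s.notch_ci
        assert (s.median - lo) == pytest.approx(hi - s.median)

    def test_notch_formula(self):
        vals = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        s = group_summary(vals)
        half = 1.57 * s.iqr / math.sqrt(len(vals))
        assert s.notch_ci == pytest.approx((s.median - half, s.median + half))

    def test_whiskers_are_percentiles(self):
        vals = list(range(101))
        s = group_summary(vals)
        assert s.whiskers == (2.0, 97.0)


def test_associate_end_to_end(tiny, stoplist):
    corpus, _ = tiny
    rep = associate(corpus, stoplist)
    assert rep.n == corpus.n_students
    assert -1 <= rep.r_completion <= 1
    assert rep.completers.n + (rep.noncompleters.n if rep.noncompleters else 0) == rep.n
    d = rep.to_dict()
    assert d["quantile_convention"] == "linear interpolation"
    if rep.ks_D is not None:
        assert 0 <= rep.ks_D <= 1
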