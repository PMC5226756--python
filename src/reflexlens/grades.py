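"""Per-student reflection-effort statistics and their link to final grade.

For every student we compute the fraction of shifts with a completed
comment (at least one non-stopword word) and the mean comment length in
raw word tokens.  Grade association is assessed three ways:

* Pearson correlation of each effort statistic with the final grade,
  with the exact-null t-test t = r·sqrt(n-2)/sqrt(1-r²);
* a completer / non-completer split at a completion-fraction threshold
  (strictly greater than 0.5 by default: "more than half"), with
  notched-boxplot summaries of each group's grades;
* a two-sample Kolmogorov–Smirnov comparison of the two grade
  distributions.

Quantiles use linear interpolation throughout; the notch interval is
the standard median ± 1.57·IQR/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .corpus import Corpus, Student
from .errors import DegenerateInputError
from .preprocess import StopList, preprocess_comment

__all__ = [
    "StudentEffort",
    "GroupSummary",
    "AssociationReport",
    "student_effort",
    "effort_table",
    "pearson_r",
    "corr_t_test",
    "split_by_completion",
    "ks_2sample",
    "group_summary",
    "associate",
]


@dataclass
class StudentEffort:
    student_id: str
    n_shifts: int
    n_complete: int
    completion_fraction: float
    mean_length: float


@dataclass
class GroupSummary:
    n: int
    median: float
    iqr: float
    notch_ci: tuple[float, float]
    whiskers: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "median": self.median,
            "iqr": self.iqr,
            "notch_ci": list(self.notch_ci),
            "whiskers": list(self.whiskers),
        }


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r: float
    r_squared: float


@dataclass
class AssociationReport:
    n: int
    r_completion: float
    t_completion: float
    p_completion: float
    fit_completion: LinearFit
    r_length: float
    t_length: float
    p_length: float
    fit_length: LinearFit
    threshold: float
    completers: GroupSummary
    noncompleters: GroupSummary | None
    ks_D: float | None
    ks_p: float | None
    quantile_convention: str = "linear interpolation"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "completion_fraction": {
                "r": self.r_completion,
                "t": self.t_completion,
                "p_two_tailed": self.p_completion,
                "slope": self.fit_completion.slope,
                "intercept": self.fit_completion.intercept,
                "r_squared": self.fit_completion.r_squared,
            },
            "mean_length": {
                "r": self.r_length,
                "t": self.t_length,
                "p_two_tailed": self.p_length,
                "slope": self.fit_length.slope,
                "intercept": self.fit_length.intercept,
                "r_squared": self.fit_length.r_squared,
            },
            "split_threshold": self.threshold,
            "completers": self.completers.to_dict(),
            "noncompleters": self.noncompleters.to_dict() if self.noncompleters else None,
            "ks_D": self.ks_D,
            "ks_p": self.ks_p,
            "quantile_convention": self.quantile_convention,
        }


def student_effort(
    student: Student,
    stoplist: StopList,
    *,
    backend: str = "lemma",
    length_convention: str = "raw",
) -> StudentEffort:
    """Completion fraction and mean comment length for one student.

    ``length_convention`` is ``"raw"`` (word tokens as written, before
    stopword removal — the default reading of "number of words in each
    reflection") or ``"content"`` (surviving lemmas only).  Shifts with
    no text contribute length 0; the denominator is the number of
    shifts worked, not the number of comments written.
    """
    if not student.shifts:
        raise ValueError(f"student {student.student_id!r} has no shifts")
    if length_convention not in {"raw", "content"}:
        raise ValueError(f"unknown length convention {length_convention!r}")
    n_complete = 0
    lengths = []
    for shift in student.shifts:
        pc = preprocess_comment(shift.raw_text, stoplist, backend=backend)
        if pc.complete:
            n_complete += 1
        lengths.append(
            len(pc.tokens) if length_convention == "raw" else len(pc.content_lemmas)
        )
    n = len(student.shifts)
    return StudentEffort(
        student_id=student.student_id,
        n_shifts=n,
        n_complete=n_complete,
        completion_fraction=n_complete / n,
        mean_length=float(np.mean(lengths)),
    )


def effort_table(
    corpus: Corpus, stoplist: StopList, *, backend: str = "lemma",
    length_convention: str = "raw",
):
    """Per-student effort statistics plus grade, as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for student in corpus.students:
        eff = student_effort(
            student, stoplist, backend=backend, length_convention=length_convention
        )
        rows.append(
            {
                "student_id": eff.student_id,
                "n_shifts": eff.n_shifts,
                "n_complete": eff.n_complete,
                "completion_fraction": eff.completion_fraction,
                "mean_length": eff.mean_length,
                "final_grade": student.final_grade,
            }
        )
    return pd.DataFrame(rows)


def pearson_r(x, y) -> LinearFit:
    """Sample Pearson correlation plus the least-squares line.

    Raises :class:`DegenerateInputError` for fewer than 3 points or a
    zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D vectors")
    if x.size < 3:
        raise DegenerateInputError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    fit = stats.linregress(x, y)
    return LinearFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue) ** 2,
    )


def corr_t_test(r: float, n: int) -> tuple[float, float]:
    """Two-tailed t-test of a Pearson correlation against zero.

    t = r·sqrt(n-2)/sqrt(1-r²) on n-2 degrees of freedom.  |r| = 1
    returns an infinite t with p = 0.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 for the correlation t-test, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return float(np.sign(r) * np.inf), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(t), float(p)


def split_by_completion(
    efforts: list[StudentEffort], grades, threshold: float = 0.5
) -> tuple[list[tuple[StudentEffort, float]], list[tuple[StudentEffort, float]]]:
    """Partition students into completers (fraction strictly > threshold,
    "more than half") and non-completers (<= threshold)."""
    grades = list(grades)
    if not efforts:
        raise ValueError("no students to split")
    if len(efforts) != len(grades):
        raise ValueError("efforts and grades are not aligned")
    completers, noncompleters = [], []
    for eff, g in zip(efforts, grades):
        (completers if eff.completion_fraction > threshold else noncompleters).append((eff, g))
    return completers, noncompleters


def ks_2sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    D = sup |ECDF_a - ECDF_b|; the p-value is exact when both samples
    have n <= 25 and asymptotic otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (a.size <= 25 and b.size <= 25) else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_summary(values) -> GroupSummary:
    """Notched-boxplot summary: median, IQR, notch CI, 2nd/97th whiskers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    median = float(np.median(v))
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation
    iqr = float(q3 - q1)
    half = 1.57 * iqr / np.sqrt(v.size)
    lo, hi = np.percentile(v, [2, 97])
    return GroupSummary(
        n=int(v.size),
        median=median,
        iqr=iqr,
        notch_ci=(median - half, median + half),
        whiskers=(float(lo), float(hi)),
    )


def associate(
    corpus: Corpus,
    stoplist: StopList,
    *,
    threshold: float = 0.5,
    backend: str = "lemma",
    length_convention: str = "raw",
) -> AssociationReport:
    """Full grade-association analysis over a corpus."""
    efforts = [
        student_effort(s, stoplist, backend=backend, length_convention=length_convention)
        for s in corpus.students
    ]
    grades = [s.final_grade for s in corpus.students]
    fractions = [e.completion_fraction for e in efforts]
    lengths = [e.mean_length for e in efforts]

    fit_c = pearson_r(fractions, grades)
    t_c, p_c = corr_t_test(fit_c.r, len(grades))
    fit_l = pearson_r(lengths, grades)
    t_l, p_l = corr_t_test(fit_l.r, len(grades))

    completers, noncompleters = split_by_completion(efforts, grades, threshold)
    comp_grades = [g for _, g in completers]
    non_grades = [g for _, g in noncompleters]
    comp_summary = group_summary(comp_grades) if comp_grades else None
    non_summary = group_summary(non_grades) if non_grades else None
    if comp_grades and non_grades:
        ks_D, ks_p = ks_2sample(comp_grades, non_grades)
    else:
        ks_D = ks_p = None
    if comp_summary is None:
        # degenerate split: report the populated group under "completers"
        comp_summary, non_summary = non_summary, None
    return AssociationReport(
        n=len(grades),
        r_completion=fit_c.r,
        t_completion=t_c,
        p_completion=p_c,
        fit_completion=fit_c,
        r_length=fit_l.r,
        t_length=t_l,
        p_length=p_l,
        fit_length=fit_l,
        threshold=threshold,
        completers=comp_summary,
        noncompleters=non_summary,
        ks_D=ks_D,
        ks_p=ks_p,
    )
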