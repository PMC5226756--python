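"""Synthetic clerkship corpora with planted, recoverable structure.

The generator emulates the study design the analysis assumes: each
student works a fixed number of shifts (14 by default), writes a short
free-text reflection after a completed shift, and receives a RIME
rating from the attending for every shift.  Planted structure:

* a per-student completion *propensity* drawn from a Beta distribution;
  each shift is completed independently with that propensity;
* a final grade on the 0-100 scale that is linear in the student's
  realised completion fraction plus Gaussian noise, clamped to [0, 100]
  (optionally calibrated so the post-clamp population correlation hits
  a requested ``target_corr``);
* category-dependent vocabularies: every rating category has a word
  pool; pools of different categories share words according to a
  pairwise overlap fraction ``rho_v`` (1 = identical pools, 0 =
  disjoint).  Comment tokens mix stopwords, shared core-vocabulary
  words and category words, with Zipf-distributed frequencies.

Words are synthetic symbols (``w0001`` ...) chosen so the text pipeline
passes them through unchanged; real clinical language is out of scope.
The ground truth (propensities, planted correlation, expected pairwise
vocabulary Jaccard) is returned alongside the corpus and is never read
by the analysis modules.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .corpus import Corpus, RimeRating, ShiftRecord, Student, RIME_ORDER

__all__ = ["SyntheticConfig", "GroundTruth", "generate_corpus", "make_fixture",
           "fixture_config", "FIXTURE_NAMES"]

_HYBRIDS = [("Reporter", "Interpreter"), ("Interpreter", "Manager"), ("Manager", "Educator")]

# Frequent English function words used as stopword filler in generated
# comments; all appear in the bundled default stoplist.
_STOP_FILL = (
    "the of and to a in that it was for on with as at by this but from or "
    "had not are were be have has they you we i so if about out up what when"
).split()


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs.  Defaults describe the emulated study:
    14 shifts per student, roughly two-thirds mean completion, grades in
    the 70-90 band rising with completion, short comments of ~12 words
    of which ~40% are stopwords."""

    n_students: int = 116
    shifts_per_student: int = 14
    completion_ab: tuple[float, float] = (2.0, 1.0)
    grade_intercept: float = 72.0
    grade_slope: float = 12.0
    grade_noise_sd: float = 5.0
    target_corr: float | None = None
    category_probs: dict = field(
        default_factory=lambda: {
            "Inadequate": 0.02,
            "Reporter": 0.18,
            "Interpreter": 0.28,
            "Manager": 0.28,
            "Educator": 0.24,
        }
    )
    hybrid_rate: float = 0.10
    core_size: int = 60
    per_category_size: int = 40
    rho_v: float | dict = 0.25
    zipf_s: float = 1.1
    category_weight: float = 0.5
    comment_len: float = 12.0
    stopword_fill: float = 0.4
    seed: int = 0

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        if isinstance(d["rho_v"], dict):
            d["rho_v"] = {"|".join(sorted(k)): v for k, v in d["rho_v"].items()}
        d["completion_ab"] = list(d["completion_ab"])
        from pathlib import Path

        Path(path).write_text(json.dumps(d, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        from pathlib import Path

        d = json.loads(Path(path).read_text(encoding="utf-8"))
        if isinstance(d.get("rho_v"), dict):
            d["rho_v"] = {tuple(k.split("|")): v for k, v in d["rho_v"].items()}
        d["completion_ab"] = tuple(d["completion_ab"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted parameters stored alongside a generated corpus."""

    propensities: dict[str, float]
    planted_corr: float
    expected_pair_jaccard: dict[tuple[str, str], float]
    category_pools: dict[str, list[str]]
    separability: float
    config: SyntheticConfig


def _zipf_probs(n: int, s: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-s)
    return w / w.sum()


def _pair_rho(rho_v, a: str, b: str) -> float:
    if isinstance(rho_v, dict):
        return float(rho_v.get((a, b), rho_v.get((b, a), 0.0)))
    return float(rho_v)


def _build_pools(config: SyntheticConfig) -> tuple[dict[str, list[str]], dict]:
    """Category word pools with planted pairwise overlap.

    ``rho_v`` is the fraction of each category's pool shared with the
    partner; shared blocks for distinct pairs are disjoint, so a pool's
    shares must sum to at most its size.  When every pair has rho 1 the
    pools are one and the same.
    """
    cats = list(RIME_ORDER) + ["Inadequate"]
    size = config.per_category_size
    pairs = [(a, b) for i, a in enumerate(RIME_ORDER) for b in RIME_ORDER[i + 1:]]
    rhos = {p: _pair_rho(config.rho_v, *p) for p in pairs}
    for p, r in rhos.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rho_v for pair {p} must lie in [0, 1], got {r}")

    counter = iter(range(10 ** 6))

    def fresh(n):
        return [f"w{next(counter):04d}" for _ in range(n)]

    pools: dict[str, list[str]] = {}
    if all(r == 1.0 for r in rhos.values()) and pairs:
        shared = fresh(size)
        for c in RIME_ORDER:
            pools[c] = list(shared)
    else:
        shares = {p: int(round(rhos[p] * size)) for p in pairs}
        load = {c: sum(s for p, s in shares.items() if c in p) for c in RIME_ORDER}
        over = [c for c in RIME_ORDER if load[c] > size]
        if over:
            raise ValueError(
                f"infeasible rho_v: categories {over} would need more shared "
                f"words than their pool size {size}"
            )
        blocks = {p: fresh(s) for p, s in shares.items()}
        for c in RIME_ORDER:
            words: list[str] = []
            for p in pairs:
                if c in p:
                    words.extend(blocks[p])
            words.extend(fresh(size - len(words)))
            pools[c] = words
    pools["Inadequate"] = fresh(size)

    expected = {}
    for (a, b) in pairs:
        inter = len(set(pools[a]) & set(pools[b]))
        union = len(set(pools[a]) | set(pools[b]))
        expected[(a, b)] = inter / union if union else 0.0
    mean_overlap = float(np.mean(list(expected.values()))) if expected else 0.0
    separability = config.category_weight * (1.0 - mean_overlap)
    _ = cats
    return pools, {"expected": expected, "separability": separability}


@lru_cache(maxsize=256)
def _calibrate_slope(
    ab: tuple[float, float],
    shifts_per_student: int,
    intercept: float,
    noise_sd: float,
    rho: float,
) -> float:
    """Slope giving the requested post-clamp correlation, by bisection.

    Clamping grades to [0, 100] attenuates the correlation, so the
    analytic pre-clamp slope is only a starting bracket; the search
    evaluates the realised correlation on a large simulated draw of
    completion fractions.  The draw uses a fixed internal stream: the
    calibrated slope is a property of the planted model, shared by
    every corpus generated from the same parameters.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"target_corr must lie strictly inside (-1, 1), got {rho}")
    if rho == 0.0:
        return 0.0
    rng = np.random.default_rng(987654321)
    a, b = ab
    m = 20000
    props = rng.beta(a, b, size=m)
    frac = rng.binomial(shifts_per_student, props) / shifts_per_student
    noise = rng.normal(0.0, noise_sd, size=m)

    def realized(slope: float) -> float:
        g = np.clip(intercept + slope * frac + noise, 0.0, 100.0)
        if np.ptp(g) == 0:
            return 0.0
        return float(np.corrcoef(frac, g)[0, 1])

    sd_f = frac.std()
    if sd_f == 0:
        raise ValueError("completion fractions are degenerate; cannot calibrate")
    target = abs(rho)
    guess = noise_sd * target / (sd_f * np.sqrt(1 - target ** 2))
    lo, hi = 0.0, max(guess * 4, 1.0)
    while realized(hi) < target and hi < 1e5:
        hi *= 2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    slope = 0.5 * (lo + hi)
    return slope if rho > 0 else -slope


def generate_corpus(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    """Draw one corpus (and its ground truth) from the planted model.

    Fully reproducible: the same config (seed included) yields a
    byte-identical corpus.
    """
    rng = np.random.default_rng(config.seed)
    pools, meta = _build_pools(config)

    if config.target_corr is not None:
        slope = _calibrate_slope(
            tuple(config.completion_ab), config.shifts_per_student,
            config.grade_intercept, config.grade_noise_sd, float(config.target_corr),
        )
        planted_corr = float(config.target_corr)
    else:
        slope = config.grade_slope
        # realised correlation implied by slope/noise, pre-clamp analytic
        a, b = config.completion_ab
        var_p = a * b / ((a + b) ** 2 * (a + b + 1))
        mean_p = a / (a + b)
        n_sh = config.shifts_per_student
        var_f = var_p + mean_p * (1 - mean_p) / n_sh - var_p / n_sh
        denom = np.sqrt(slope ** 2 * var_f + config.grade_noise_sd ** 2)
        planted_corr = float(slope * np.sqrt(var_f) / denom) if denom > 0 else 0.0

    base_cats = list(config.category_probs)
    base_p = np.array([config.category_probs[c] for c in base_cats], dtype=float)
    if (base_p < 0).any():
        raise ValueError("category probabilities must be non-negative")
    base_p = base_p / base_p.sum()
    if not 0.0 <= config.hybrid_rate <= 1.0:
        raise ValueError("hybrid_rate must lie in [0, 1]")
    if not 0.0 <= config.stopword_fill <= 1.0:
        raise ValueError("stopword_fill must lie in [0, 1]")

    core = [f"c{j:04d}" for j in range(config.core_size)]
    core_probs = _zipf_probs(len(core), config.zipf_s) if core else None
    pool_probs = {
        c: _zipf_probs(len(p), config.zipf_s) if p else None for c, p in pools.items()
    }
    stop_probs = _zipf_probs(len(_STOP_FILL), config.zipf_s)

    def draw_rating() -> RimeRating:
        if rng.random() < config.hybrid_rate:
            pair = _HYBRIDS[rng.integers(len(_HYBRIDS))]
            return RimeRating(categories=pair, hybrid=True)
        cat = base_cats[rng.choice(len(base_cats), p=base_p)]
        return RimeRating(categories=(cat,), hybrid=False)

    def draw_content_word(rating: RimeRating) -> str:
        cat = rating.categories[int(rng.integers(len(rating.categories)))]
        pool, pp = pools[cat], pool_probs[cat]
        use_category = pp is not None and (
            core_probs is None or rng.random() < config.category_weight
        )
        if use_category:
            return pool[int(rng.choice(len(pool), p=pp))]
        if core_probs is None:
            raise ValueError("both core and category vocabularies are empty")
        return core[int(rng.choice(len(core), p=core_probs))]

    def draw_comment(rating: RimeRating) -> str:
        length = max(1, int(rng.poisson(config.comment_len)))
        words = []
        for _ in range(length):
            if rng.random() < config.stopword_fill:
                words.append(_STOP_FILL[int(rng.choice(len(_STOP_FILL), p=stop_probs))])
            else:
                words.append(draw_content_word(rating))
        if all(w in _STOP_FILL for w in words):
            # a completed shift must contain at least one content word,
            # so the completion predicate measures the planted propensity
            words[int(rng.integers(len(words)))] = draw_content_word(rating)
        return " ".join(words) + "."

    students = []
    propensities = {}
    a, b = config.completion_ab
    for i in range(config.n_students):
        sid = f"S{i + 1:04d}"
        prop = float(rng.beta(a, b))
        propensities[sid] = prop
        shifts = []
        n_complete = 0
        for shift_index in range(1, config.shifts_per_student + 1):
            rating = draw_rating()
            completed = rng.random() < prop
            if completed:
                n_complete += 1
                text = draw_comment(rating)
            else:
                text = ""
            shifts.append(ShiftRecord(shift_index=shift_index, raw_text=text, rating=rating))
        frac = n_complete / config.shifts_per_student
        grade = config.grade_intercept + slope * frac + rng.normal(0.0, config.grade_noise_sd)
        grade = float(np.clip(grade, 0.0, 100.0))
        students.append(Student(student_id=sid, final_grade=grade, shifts=shifts))

    corpus = Corpus(students=students, metadata={"generator": "reflexlens.synthetic",
                                                "seed": config.seed})
    truth = GroundTruth(
        propensities=propensities,
        planted_corr=planted_corr,
        expected_pair_jaccard=meta["expected"],
        category_pools=pools,
        separability=meta["separability"],
        config=config,
    )
    return corpus, truth


FIXTURE_NAMES = ("tiny", "calibration", "separable", "null")

_FIXTURES: dict[str, SyntheticConfig] = {
    # 6 students, small vocabulary: every downstream statistic is small
    # enough to check by hand.
    "tiny": SyntheticConfig(
        n_students=6, core_size=12, per_category_size=8, comment_len=6.0,
        stopword_fill=0.4, seed=42,
    ),
    # exchangeable categories: identical pools (rho_v = 1), so category
    # labels carry no vocabulary information — the null of the Jaccard
    # resampling test holds by construction.
    "calibration": SyntheticConfig(
        n_students=40, rho_v=1.0, core_size=30, per_category_size=40,
        category_weight=0.5, comment_len=10.0, hybrid_rate=0.0,
        category_probs={"Inadequate": 0.0, "Reporter": 0.25, "Interpreter": 0.25,
                        "Manager": 0.25, "Educator": 0.25},
        seed=7,
    ),
    # disjoint category vocabularies, no shared core: top-k vocabularies
    # of different categories cannot overlap.
    "separable": SyntheticConfig(
        n_students=400, rho_v=0.0, core_size=0, per_category_size=40,
        category_weight=1.0, comment_len=12.0, stopword_fill=0.3,
        category_probs={"Inadequate": 0.0, "Reporter": 0.25, "Interpreter": 0.25,
                        "Manager": 0.25, "Educator": 0.25},
        hybrid_rate=0.1, seed=11,
    ),
    # no completion-grade association planted.
    "null": SyntheticConfig(n_students=300, target_corr=0.0, seed=13),
}


def fixture_config(name: str) -> SyntheticConfig:
    """The frozen configuration behind a named fixture (a copy; callers
    may ``dataclasses.replace`` it for scaled variants)."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")
    return dataclasses.replace(_FIXTURES[name])


def make_fixture(name: str) -> tuple[Corpus, GroundTruth]:
    """Generate one of the frozen named test corpora."""
    return generate_corpus(fixture_config(name))
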