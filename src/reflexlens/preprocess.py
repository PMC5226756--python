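"""Text normalisation for reflective comments, and the completion predicate.

The pipeline applies, in order:

1. lower-casing,
2. tokenisation into word-character runs (punctuation discarded, so
   clinical shorthand like ``s/p`` splits into ``s``, ``p``),
3. stopword removal on surface tokens,
4. part-of-speech-keyed lemmatisation of the survivors.

A comment is *complete* when at least one lemma survives stopword
removal — i.e. it contains at least one content word.  That predicate
is the unit of the completion-fraction statistic downstream.

The tokenizer is a deterministic regular expression, not a learned
model, so results are reproducible across versions and platforms.  The
part-of-speech tagger and lemmatizer are likewise deterministic: a
function-word/suffix tagger that falls back to noun, and a rule-based
inflectional lemmatizer with an irregular-forms lexicon.  A Porter
stemmer is available as an opt-in derivational backend for analyses
that want e.g. "infection" and "infect" collapsed — that mapping is
derivational, beyond what inflectional lemmatisation does.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .errors import ConfigurationError

__all__ = [
    "StopList",
    "load_stoplist",
    "default_stoplist",
    "tokenize",
    "pos_tag",
    "lemmatize",
    "porter_stem",
    "ProcessedComment",
    "preprocess_comment",
]

_WORD_RE = re.compile(r"[^\W_]+", re.UNICODE)

_VOWELS = frozenset("aeiou")


# ---------------------------------------------------------------------------
# Stoplist

@dataclass(frozen=True)
class StopList:
    """A set of lowercase stopwords plus the provenance of its files."""

    words: frozenset[str]
    source_files: tuple[str, ...] = ()

    def __contains__(self, token: str) -> bool:
        return token in self.words

    def __len__(self) -> int:
        return len(self.words)


def _read_stop_file(path: Path) -> set[str]:
    words = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        word = line.lower()
        if any(ch.isspace() for ch in word):
            raise ConfigurationError(f"{path}: stopword {line!r} contains whitespace")
        words.add(word)
    return words


def load_stoplist(paths: list[str | Path] | None) -> StopList:
    """Union the stopword files at ``paths`` (lowercased, deduplicated).

    Passing ``None`` is a configuration error: running with no stoplist
    silently would change every downstream count, so an intentionally
    empty stoplist must be requested explicitly with ``[]``... which is
    accepted and yields an empty :class:`StopList`.
    """
    if paths is None:
        raise ConfigurationError(
            "no stoplist given; pass an explicit empty list to run without one"
        )
    words: set[str] = set()
    sources = []
    for p in paths:
        p = Path(p)
        words |= _read_stop_file(p)
        sources.append(str(p))
    return StopList(words=frozenset(words), source_files=tuple(sources))


def default_stoplist() -> StopList:
    """The package's bundled standard English function-word list."""
    ref = resources.files("reflexlens.data") / "stopwords_en.txt"
    with resources.as_file(ref) as path:
        words = _read_stop_file(path)
    return StopList(words=frozenset(words), source_files=("<bundled:stopwords_en.txt>",))


# ---------------------------------------------------------------------------
# Tokenisation

def tokenize(text: str) -> list[str]:
    """Lowercase ``text`` and split it into word-character runs.

    Punctuation-only material disappears; intra-word punctuation splits
    the word ("c/o" -> ["c", "o"]). The empty string yields [].
    """
    return _WORD_RE.findall(text.lower())


# ---------------------------------------------------------------------------
# Coarse part-of-speech tagging

_POS_TAGS = ("noun", "verb", "adjective", "adverb", "other")

# Closed-class function words tagged "other"; overlaps the default
# stoplist deliberately (both describe closed-class English).
_FUNCTION_WORDS = frozenset(
    """a an the and or but if while although because so as of at by for with
    about against between into through during before after above below to from
    up down in out on off over under again further then once here there when
    where why how all any both each few more most other some such no nor not
    only own same than too very can will just should now i me my we our you
    your he him his she her it its they them their this that these those am is
    are was were be been being have has had do does did would could might must
    shall may""".split()
)

_VERB_LEXICON = frozenset(
    """be have do go see say make take come know think feel get give find tell
    ask work seem leave call keep let begin help talk turn start show hear play
    run move like live believe hold bring happen write sit stand lose pay meet
    learn teach treat diagnose examine admit discharge present complain manage
    order review discuss observe perform assess evaluate improve practice
    reflect was were been being went gone saw seen said made took taken came
    knew known thought felt got gave given found told kept began brought wrote
    written sat stood lost paid met learned learnt taught ran""".split()
)

_ADJ_LEXICON = frozenset(
    """good better best bad worse worst big small high low new old young hard
    easy difficult challenging unexpected interesting important acute chronic
    severe mild stable unstable critical busy slow fast first last next great
    common rare clinical medical sick ill unwell""".split()
)

_NOT_ADVERB = frozenset(
    "family supply apply reply fly ally belly jelly rally italy july early".split()
)

_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "ish", "less", "ical")


def _tag_one(token: str) -> str:
    if token in _FUNCTION_WORDS:
        return "other"
    if token in _VERB_LEXICON:
        return "verb"
    if token in _ADJ_LEXICON:
        return "adjective"
    if token.endswith("ly") and len(token) > 3 and token not in _NOT_ADVERB:
        return "adverb"
    if token.endswith("ing") and len(token) > 4:
        return "verb"
    if token.endswith("ed") and len(token) > 3:
        return "verb"
    if token.endswith(_ADJ_SUFFIXES) and len(token) > 4:
        return "adjective"
    return "noun"  # open-class default


def pos_tag(tokens: list[str]) -> list[tuple[str, str]]:
    """Tag each lowercase token with a coarse part of speech.

    Tags are drawn from {noun, verb, adjective, adverb, other}; unknown
    open-class words default to noun, the safest choice for
    lemmatisation of clinical vocabulary.
    """
    return [(t, _tag_one(t)) for t in tokens]


# ---------------------------------------------------------------------------
# Lemmatisation (rule-based inflectional, with irregulars)

_IRREGULAR_NOUNS = {
    "men": "man", "women": "woman", "children": "child", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "criteria": "criterion",
    "diagnoses": "diagnosis", "analyses": "analysis", "indices": "index",
    "lives": "life", "selves": "self",
}

_IRREGULAR_VERBS = {
    "am": "be", "is": "be", "are": "be", "was": "be", "were": "be",
    "been": "be", "being": "be", "has": "have", "had": "have",
    "does": "do", "did": "do", "done": "do", "went": "go", "gone": "go",
    "said": "say", "made": "make", "took": "take", "taken": "take",
    "saw": "see", "seen": "see", "got": "get", "gave": "give",
    "given": "give", "knew": "know", "known": "know", "thought": "think",
    "felt": "feel", "found": "find", "told": "tell", "kept": "keep",
    "met": "meet", "taught": "teach", "learnt": "learn", "ran": "run",
    "came": "come", "began": "begin", "begun": "begin", "wrote": "write",
    "written": "write", "brought": "bring", "lost": "lose", "paid": "pay",
    "sat": "sit", "stood": "stand", "left": "leave", "lying": "lie",
}

_IRREGULAR_ADJS = {"better": "good", "best": "good", "worse": "bad", "worst": "bad"}


def _is_vowel(ch: str) -> bool:
    return ch in _VOWELS


def _syllable_groups(word: str) -> int:
    groups = 0
    prev_vowel = False
    for ch in word:
        v = _is_vowel(ch) or ch == "y"
        if v and not prev_vowel:
            groups += 1
        prev_vowel = v
    return groups


def _fix_stripped_stem(stem: str) -> str:
    """Repair a stem left by removing -ed/-ing/-er: undouble a doubled
    final consonant, or restore a dropped final 'e' where spelling rules
    imply one."""
    if len(stem) >= 2 and stem[-1] == stem[-2] and not _is_vowel(stem[-1]) and stem[-1] not in "lsz":
        return stem[:-1]
    if len(stem) >= 2 and stem[-1] in "cgsuvz" and _is_vowel(stem[-2]):
        return stem + "e"  # manag -> manage, us -> use, notic -> notice
    if (
        len(stem) >= 3
        and not _is_vowel(stem[-1]) and stem[-1] not in "wxy"
        and _is_vowel(stem[-2]) and not _is_vowel(stem[-3])
        and _syllable_groups(stem) == 1
    ):
        return stem + "e"  # car -> care, mak -> make (monosyllabic CVC)
    return stem


def _strip_plural(word: str) -> str:
    if len(word) < 4 or not word.endswith("s"):
        return word
    if word.endswith(("ss", "us", "is")):
        return word
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("xes", "zes", "ches", "shes", "sses", "oes")):
        return word[:-2]
    return word[:-1]


def _lemmatize_one(token: str, pos: str) -> str:
    if pos == "noun":
        return _IRREGULAR_NOUNS.get(token) or _strip_plural(token)
    if pos == "verb":
        irr = _IRREGULAR_VERBS.get(token)
        if irr:
            return irr
        if token.endswith("ies") and len(token) > 4:
            return token[:-3] + "y"
        if token.endswith("ied") and len(token) > 4:
            return token[:-3] + "y"
        if token.endswith("ed") and len(token) > 3:
            return _fix_stripped_stem(token[:-2])
        if token.endswith("ing") and len(token) > 4:
            return _fix_stripped_stem(token[:-3])
        return _strip_plural(token)
    if pos == "adjective":
        irr = _IRREGULAR_ADJS.get(token)
        if irr:
            return irr
        if token.endswith("ier") and len(token) > 4:
            return token[:-3] + "y"
        if token.endswith("iest") and len(token) > 5:
            return token[:-4] + "y"
        if token.endswith("est") and len(token) > 4:
            return _fix_stripped_stem(token[:-3])
        if token.endswith("er") and len(token) > 3:
            return _fix_stripped_stem(token[:-2])
        return token
    return token  # adverbs and function words are not inflected here


@lru_cache(maxsize=65536)
def _lemma_cached(token: str, pos: str) -> str:
    return _lemmatize_one(token, pos)


def lemmatize(tagged: list[tuple[str, str]]) -> list[str]:
    """Map each (token, coarse_pos) pair to its base form.

    Inflectional only: plural nouns, verb -s/-ed/-ing forms and
    comparative/superlative adjectives are reduced; tokens the rules do
    not recognise pass through unchanged.
    """
    return [_lemma_cached(tok, pos) for tok, pos in tagged]


# ---------------------------------------------------------------------------
# Porter stemmer (opt-in derivational backend)

def _m(word: str) -> int:
    """Porter's measure: number of VC sequences in the word."""
    cv = []
    for i, ch in enumerate(word):
        v = _is_vowel(ch) or (ch == "y" and i > 0 and not _is_vowel(word[i - 1]))
        cv.append("v" if v else "c")
    return "".join(cv).count("vc")


def _contains_vowel(word: str) -> bool:
    return any(_is_vowel(ch) or (ch == "y" and i > 0 and not _is_vowel(word[i - 1]))
               for i, ch in enumerate(word))


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    c1, v, c2 = word[-3], word[-2], word[-1]
    return (not _is_vowel(c1)) and _is_vowel(v) and (not _is_vowel(c2)) and c2 not in "wxy"


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = ["al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
          "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize"]


def porter_stem(word: str) -> str:
    """Classic Porter suffix-stripping stemmer.

    Derivational: collapses e.g. "infection", "infections", "infected"
    and "infect" onto the stem "infect", which inflectional
    lemmatisation deliberately does not do.
    """
    w = word.lower()
    if len(w) <= 2:
        return w
    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]
    # step 1b
    flag = False
    if w.endswith("eed"):
        if _m(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _contains_vowel(w[:-2]):
        w, flag = w[:-2], True
    elif w.endswith("ing") and _contains_vowel(w[:-3]):
        w, flag = w[:-3], True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif len(w) >= 2 and w[-1] == w[-2] and not _is_vowel(w[-1]) and w[-1] not in "lsz":
            w = w[:-1]
        elif _m(w) == 1 and _ends_cvc(w):
            w += "e"
    # step 1c
    if w.endswith("y") and _contains_vowel(w[:-1]):
        w = w[:-1] + "i"
    # step 2
    for suf, rep in _STEP2:
        if w.endswith(suf):
            if _m(w[: -len(suf)]) > 0:
                w = w[: -len(suf)] + rep
            break
    # step 3
    for suf, rep in _STEP3:
        if w.endswith(suf):
            if _m(w[: -len(suf)]) > 0:
                w = w[: -len(suf)] + rep
            break
    # step 4
    for suf in _STEP4:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if suf == "ion" and (not stem or stem[-1] not in "st"):
                break
            if _m(stem) > 1:
                w = stem
            break
    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        if _m(stem) > 1 or (_m(stem) == 1 and not _ends_cvc(stem)):
            w = stem
    # step 5b
    if len(w) >= 2 and w.endswith("ll") and _m(w) > 1:
        w = w[:-1]
    return w


# ---------------------------------------------------------------------------
# The assembled comment pipeline

@dataclass
class ProcessedComment:
    """Normalised representation of one shift's comment."""

    raw_text: str
    tokens: list[str] = field(default_factory=list)
    content_lemmas: list[str] = field(default_factory=list)
    complete: bool = False


def preprocess_comment(
    raw: str,
    stoplist: StopList,
    *,
    backend: str = "lemma",
    second_stop_pass: bool = False,
) -> ProcessedComment:
    """Run the four normalisation steps on one raw comment.

    Stopwords are matched on surface tokens *before* lemmatisation, so
    an inflected variant of a stopword that is not itself listed
    survives; ``second_stop_pass=True`` adds a post-lemma re-filter for
    pipelines that want that closed.

    ``backend`` selects the word-normaliser: ``"lemma"`` (default,
    inflectional rules) or ``"porter"`` (derivational stemming).
    """
    if backend not in {"lemma", "porter"}:
        raise ValueError(f"unknown preprocessing backend {backend!r}")
    tokens = tokenize(raw)
    content = [t for t in tokens if t not in stoplist]
    if backend == "porter":
        lemmas = [porter_stem(t) for t in content]
    else:
        lemmas = lemmatize(pos_tag(content))
    if second_stop_pass:
        lemmas = [l for l in lemmas if l not in stoplist]
    return ProcessedComment(
        raw_text=raw,
        tokens=tokens,
        content_lemmas=lemmas,
        complete=len(lemmas) >= 1,
    )
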