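"""Typed exceptions raised by the analysis stages.

Every stage failure that a caller might want to branch on gets its own
class; all of them descend from ``ReflexLensError`` so a pipeline driver
can catch the family in one clause.
"""


class ReflexLensError(Exception):
    """Base class for all package errors."""


class FormatError(ReflexLensError, ValueError):
    """A file does not match the documented dialect (e.g. missing column)."""


class IntegrityError(ReflexLensError, ValueError):
    """Data violates a corpus invariant (e.g. duplicate shift index)."""


class RimeLabelError(ReflexLensError, ValueError):
    """An evaluation label cannot be parsed into a RIME rating."""


class ConfigurationError(ReflexLensError, ValueError):
    """A pipeline configuration is invalid (e.g. an accidentally empty stoplist)."""


class EmptyCategoryError(ReflexLensError, ValueError):
    """A rating category has no eligible completed comments."""

    def __init__(self, category: str, message: str | None = None):
        self.category = category
        super().__init__(message or f"no eligible completed comments for category {category!r}")


class DegenerateInputError(ReflexLensError, ValueError):
    """Input is degenerate for the requested statistic (e.g. zero variance)."""


class StratificationError(ReflexLensError, ValueError):
    """A class is too rare to stratify into the requested number of folds.

    This is the practical face of "insufficient data to train a classifier":
    with fewer members than folds, stratified cross-validation is undefined.
    """

    def __init__(self, category: str, count: int, folds: int):
        self.category = category
        self.count = count
        self.folds = folds
        super().__init__(
            f"class {category!r} has {count} completed comments, fewer than "
            f"{folds} folds; stratified cross-validation is impossible"
        )
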