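"""Corpus data model and readers/writers for its file formats.

A corpus is a collection of students; each student has a final clerkship
grade on the 0-100 scale and a list of per-shift records.  A shift record
holds the raw reflective comment verbatim (possibly empty: the student
wrote nothing, or nothing legible) and, when present, the attending's
RIME rating for that shift.

RIME is the Reporter < Interpreter < Manager < Educator ladder used to
rate a trainee's clinical functioning; some evaluation forms print
"Superior" for the top rung, and an attending may circle two adjacent
rungs, producing a hybrid rating such as "Reporter-Interpreter".
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError, IntegrityError, RimeLabelError

__all__ = [
    "RIME_ORDER",
    "RimeRating",
    "ShiftRecord",
    "Student",
    "Corpus",
    "parse_rime_label",
    "read_corpus",
    "write_corpus_csv",
    "write_report",
    "read_report",
]

#: Canonical bottom-to-top order of the RIME ladder. "Inadequate" sits
#: outside the ladder and can never be half of a hybrid rating.
RIME_ORDER = ("Reporter", "Interpreter", "Manager", "Educator")

BASE_CATEGORIES = ("Inadequate",) + RIME_ORDER

_ALIASES = {
    "superior": "Educator",  # some evaluation tools relabel the top rung
}


@dataclass(frozen=True)
class RimeRating:
    """One attending rating: one base category, or two adjacent ones.

    ``categories`` is stored ladder-ordered; ``hybrid`` is true iff two
    categories were circled.
    """

    categories: tuple[str, ...]
    hybrid: bool

    def __post_init__(self):
        if not 1 <= len(self.categories) <= 2:
            raise RimeLabelError(f"rating must have 1 or 2 categories, got {self.categories!r}")
        if self.hybrid != (len(self.categories) == 2):
            raise RimeLabelError("hybrid flag inconsistent with category count")
        for c in self.categories:
            if c not in BASE_CATEGORIES:
                raise RimeLabelError(f"unknown category {c!r}")
        if self.hybrid:
            a, b = self.categories
            if "Inadequate" in (a, b):
                raise RimeLabelError("'Inadequate' cannot be part of a hybrid rating")
            ia, ib = RIME_ORDER.index(a), RIME_ORDER.index(b)
            if ib - ia != 1:
                raise RimeLabelError(
                    f"non-adjacent hybrid {a}-{b}: hybrid ratings must straddle "
                    "neighbouring rungs of the RIME ladder"
                )

    @property
    def label(self) -> str:
        """Canonical printed form, hyphenated when hybrid."""
        return "-".join(self.categories)

    def __str__(self) -> str:
        return self.label


def parse_rime_label(label: str) -> RimeRating:
    """Parse an evaluation-form label into a :class:`RimeRating`.

    Case-insensitive; "Superior" is canonicalised to "Educator"; "-" or
    "/" separates the two halves of a hybrid.  Idempotent on canonical
    output.

    Raises
    ------
    RimeLabelError
        For an empty label, an unknown token, or a non-adjacent hybrid.
    """
    text = label.strip()
    if not text:
        raise RimeLabelError("empty rating label")
    parts = [p for p in text.replace("/", "-").split("-") if p.strip()]
    if len(parts) > 2:
        raise RimeLabelError(f"rating label {label!r} has more than two categories")
    cats = []
    for part in parts:
        key = part.strip().lower()
        canonical = _ALIASES.get(key, key.capitalize())
        if canonical not in BASE_CATEGORIES:
            raise RimeLabelError(f"unknown rating token {part.strip()!r} in label {label!r}")
        cats.append(canonical)
    if len(cats) == 2:
        if "Inadequate" in cats:
            raise RimeLabelError(f"'Inadequate' cannot be part of a hybrid rating: {label!r}")
        cats.sort(key=RIME_ORDER.index)
        if cats[0] == cats[1]:
            raise RimeLabelError(f"repeated category in hybrid label {label!r}")
    return RimeRating(categories=tuple(cats), hybrid=len(cats) == 2)


@dataclass
class ShiftRecord:
    """One shift: its 1-based index, the raw comment text (verbatim;
    empty string means no reflection was written or none was legible),
    and the attending rating when one was recorded."""

    shift_index: int
    raw_text: str = ""
    rating: RimeRating | None = None

    def __post_init__(self):
        if self.shift_index < 1:
            raise IntegrityError(f"shift_index must be >= 1, got {self.shift_index}")


@dataclass
class Student:
    """One student: opaque id, final grade on the 0-100 scale, shifts."""

    student_id: str
    final_grade: float
    shifts: list[ShiftRecord] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.final_grade <= 100.0:
            raise IntegrityError(
                f"final_grade for {self.student_id!r} must lie in [0, 100], got {self.final_grade}"
            )
        seen = set()
        for s in self.shifts:
            if s.shift_index in seen:
                raise IntegrityError(
                    f"duplicate shift_index {s.shift_index} for student {self.student_id!r}"
                )
            seen.add(s.shift_index)


@dataclass
class Corpus:
    students: list[Student] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.student_id for s in self.students]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate student ids: {dup}")

    @property
    def n_students(self) -> int:
        return len(self.students)

    def iter_shifts(self):
        """Yield (student, shift) pairs in corpus order."""
        for student in self.students:
            for shift in student.shifts:
                yield student, shift


_CSV_COLUMNS = ("student_id", "shift_index", "comment", "rating", "final_grade")


def _rows_to_corpus(rows, source: str) -> Corpus:
    students: dict[str, dict] = {}
    seen_shifts: set[tuple[str, int]] = set()
    for lineno, row in rows:
        sid = str(row["student_id"])
        try:
            shift_index = int(row["shift_index"])
        except (TypeError, ValueError):
            raise FormatError(f"{source}: row {lineno}: bad shift_index {row['shift_index']!r}")
        try:
            grade = float(row["final_grade"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{source}: row {lineno}: unparseable final_grade {row['final_grade']!r}"
            )
        if (sid, shift_index) in seen_shifts:
            raise IntegrityError(
                f"{source}: row {lineno}: duplicate (student_id, shift_index) = ({sid!r}, {shift_index})"
            )
        seen_shifts.add((sid, shift_index))
        raw_label = (row.get("rating") or "").strip()
        rating = parse_rime_label(raw_label) if raw_label else None
        comment = row.get("comment") or ""
        rec = ShiftRecord(shift_index=shift_index, raw_text=comment, rating=rating)
        entry = students.setdefault(sid, {"grade": grade, "shifts": []})
        if entry["grade"] != grade:
            raise IntegrityError(
                f"{source}: row {lineno}: student {sid!r} has conflicting grades "
                f"{entry['grade']} vs {grade}"
            )
        entry["shifts"].append(rec)
    return Corpus(
        students=[
            Student(student_id=sid, final_grade=e["grade"], shifts=e["shifts"])
            for sid, e in students.items()
        ],
        metadata={"source": source},
    )


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from CSV/TSV (one row per shift) or JSONL.

    The CSV dialect requires a header with columns ``student_id,
    shift_index, comment, rating, final_grade``; the per-student grade is
    repeated on every row.  Empty comment cells become empty raw text —
    a present row with no text is a shift without a (legible) reflection,
    which is distinct from a missing row, because completion is counted
    against the number of shifts worked.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson"} else "csv"
    if format not in {"csv", "jsonl"}:
        raise ValueError(f"unknown corpus format {format!r}")
    if format == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                obj = json.loads(line)
                missing = [c for c in _CSV_COLUMNS if c not in obj]
                if missing:
                    raise FormatError(f"{path}: line {lineno}: missing field(s) {missing}")
                rows.append((lineno, obj))
        return _rows_to_corpus(rows, str(path))
    with open(path, encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} or (
            "\t" in sample.splitlines()[0] if sample else False
        ) else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in _CSV_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        rows = [(lineno, row) for lineno, row in enumerate(reader, start=2)]
    return _rows_to_corpus(rows, str(path))


def write_corpus_csv(corpus: Corpus, path: str | Path) -> None:
    """Serialise a corpus in the CSV dialect ``read_corpus`` accepts.

    Round-trips losslessly: grades are written with ``repr`` so no
    precision is dropped, ratings in canonical hyphenated form.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for student in corpus.students:
            for shift in student.shifts:
                writer.writerow(
                    [
                        student.student_id,
                        shift.shift_index,
                        shift.raw_text,
                        shift.rating.label if shift.rating else "",
                        repr(student.final_grade),
                    ]
                )


REPORT_SECTIONS = (
    "preprocessing_summary",
    "ngram_tables",
    "jaccard_matrix",
    "grade_association",
    "classifier",
)


def write_report(results: dict, path: str | Path) -> None:
    """Write the assembled analysis report as one JSON document.

    ``results`` must contain every section in :data:`REPORT_SECTIONS`
    (a section may be ``None``, e.g. a skipped classifier).  Key order is
    stable: the five sections first, in canonical order, then any extras
    sorted by name.
    """
    missing = [k for k in REPORT_SECTIONS if k not in results]
    if missing:
        raise ValueError(f"report is missing section(s): {', '.join(missing)}")
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"report path {path} is a directory")
    ordered = {k: results[k] for k in REPORT_SECTIONS}
    for k in sorted(results):
        if k not in ordered:
            ordered[k] = results[k]
    text = json.dumps(ordered, indent=2, sort_keys=False, ensure_ascii=False)
    path.write_text(text + "\n", encoding="utf-8")


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def corpus_to_frame(corpus: Corpus):
    """Flatten a corpus to a pandas DataFrame (one row per shift)."""
    import pandas as pd

    rows = []
    for student, shift in corpus.iter_shifts():
        rows.append(
            {
                "student_id": student.student_id,
                "shift_index": shift.shift_index,
                "comment": shift.raw_text,
                "rating": shift.rating.label if shift.rating else "",
                "final_grade": student.final_grade,
            }
        )
    return pd.DataFrame(rows, columns=list(_CSV_COLUMNS))
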