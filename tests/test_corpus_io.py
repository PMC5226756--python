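import json

import pytest

from reflexlens.corpus import (
    Corpus,
    RimeRating,
    ShiftRecord,
    Student,
    parse_rime_label,
    read_corpus,
    read_report,
    write_corpus_csv,
    write_report,
)
from reflexlens.errors import FormatError, IntegrityError, RimeLabelError
from reflexlens.synthetic import make_fixture


class TestParseRimeLabel:
    @pytest.mark.parametrize(
        "label,categories,hybrid",
        [
            ("Reporter", ("Reporter",), False),
            ("Superior", ("Educator",), False),  # evaluation-tool alias
            ("superior", ("Educator",), False),
            ("reporter-interpreter", ("Reporter", "Interpreter"), True),
            ("Interpreter/Manager", ("Interpreter", "Manager"), True),
            ("manager-superior", ("Manager", "Educator"), True),
            ("  Educator  ", ("Educator",), False),
            ("Inadequate", ("Inadequate",), False),
            # ladder order restored regardless of input order
            ("Interpreter-Reporter", ("Reporter", "Interpreter"), True),
        ],
    )
    def test_parses(self, label, categories, hybrid):
        r = parse_rime_label(label)
        assert r.categories == categories
        assert r.hybrid is hybrid

    @pytest.mark.parametrize(
        "label",
        ["Observer", "", "   ", "Reporter-Manager", "Reporter-Educator",
         "Inadequate-Reporter", "Reporter-Reporter", "a-b-c"],
    )
    def test_rejects(self, label):
        with pytest.raises(RimeLabelError):
            parse_rime_label(label)

    def test_idempotent_on_canonical_output(self):
        for label in ["Superior", "interpreter/manager", "Reporter"]:
            first = parse_rime_label(label)
            again = parse_rime_label(first.label)
            assert again == first

    def test_nonadjacent_error_mentions_adjacency(self):
        with pytest.raises(RimeLabelError, match="adjacen"):
            parse_rime_label("Reporter-Manager")


class TestReadCorpus:
    HEADER = "student_id,shift_index,comment,rating,final_grade\n"

    def write(self, tmp_path, body, name="c.csv"):
        p = tmp_path / name
        p.write_text(self.HEADER + body, encoding="utf-8")
        return p

    def test_one_student_three_shifts(self, tmp_path):
        p = self.write(
            tmp_path,
            "s1,1,saw a patient,Reporter,83.0\n"
            "s1,2,,Manager,83.0\n"
            "s1,3,busy shift,Superior,83.0\n",
        )
        corpus = read_corpus(p)
        assert corpus.n_students == 1
        (student,) = corpus.students
        assert len(student.shifts) == 3
        assert student.final_grade == 83.0
        assert student.shifts[1].raw_text == ""  # empty cell preserved as a shift

    def test_hybrid_rating_cell(self, tmp_path):
        p = self.write(tmp_path, "s1,1,x,Reporter-Interpreter,80\n")
        shift = read_corpus(p).students[0].shifts[0]
        assert shift.rating.hybrid
        assert shift.rating.categories == ("Reporter", "Interpreter")

    def test_missing_comment_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("student_id,shift_index,rating,final_grade\ns1,1,Reporter,80\n")
        with pytest.raises(FormatError, match="comment"):
            read_corpus(p)

    def test_duplicate_shift_index(self, tmp_path):
        p = self.write(tmp_path, "s1,1,x,Reporter,80\ns1,1,y,Manager,80\n")
        with pytest.raises(IntegrityError, match="duplicate"):
            read_corpus(p)

    def test_unparseable_grade_names_row(self, tmp_path):
        p = self.write(tmp_path, "s1,1,x,Reporter,80\ns1,2,y,Manager,eighty\n")
        with pytest.raises(FormatError, match="row 3"):
            read_corpus(p)

    def test_jsonl(self, tmp_path):
        p = tmp_path / "c.jsonl"
        rows = [
            {"student_id": "s1", "shift_index": 1, "comment": "abc",
             "rating": "Reporter", "final_grade": 91.5},
            {"student_id": "s1", "shift_index": 2, "comment": "",
             "rating": "", "final_grade": 91.5},
        ]
        p.write_text("\n".join(json.dumps(r) for r in rows) + "\n")
        corpus = read_corpus(p)
        assert corpus.students[0].final_grade == 91.5
        assert corpus.students[0].shifts[1].rating is None


def test_csv_round_trip_lossless(tmp_path):
    corpus, _ = make_fixture("tiny")
    path = tmp_path / "tiny.csv"
    write_corpus_csv(corpus, path)
    back = read_corpus(path)
    assert back.n_students == corpus.n_students
    for orig, re_read in zip(corpus.students, back.students):
        assert re_read.student_id == orig.student_id
        assert re_read.final_grade == orig.final_grade  # repr round-trip, bit exact
        for a, b in zip(orig.shifts, re_read.shifts):
            assert (a.shift_index, a.raw_text) == (b.shift_index, b.raw_text)
            assert (a.rating.label if a.rating else None) == (
                b.rating.label if b.rating else None
            )


class TestDomainInvariants:
    def test_grade_range_enforced(self):
        with pytest.raises(IntegrityError):
            Student(student_id="s", final_grade=101.0)

    def test_duplicate_student_ids_rejected(self):
        s = [Student(student_id="s", final_grade=80.0),
             Student(student_id="s", final_grade=81.0)]
        with pytest.raises(IntegrityError):
            Corpus(students=s)

    def test_hybrid_flag_must_match_count(self):
        with pytest.raises(RimeLabelError):
            RimeRating(categories=("Reporter",), hybrid=True)

    def test_shift_index_positive(self):
        with pytest.raises(IntegrityError):
            ShiftRecord(shift_index=0)


class TestWriteReport:
    MINIMAL = {
        "preprocessing_summary": {"n": 1},
        "ngram_tables": {},
        "jaccard_matrix": [],
        "grade_association": {},
        "classifier": None,
    }

    def test_all_sections_present_and_ordered(self, tmp_path):
        p = tmp_path / "r.json"
        write_report(self.MINIMAL, p)
        text = p.read_text()
        order = [text.index(f'"{k}"') for k in self.MINIMAL]
        assert order == sorted(order)

    def test_round_trip(self, tmp_path):
        p = tmp_path / "r.json"
        write_report(self.MINIMAL, p)
        assert read_report(p) == self.MINIMAL

    def test_missing_section_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="classifier"):
            write_report({k: v for k, v in self.MINIMAL.items() if k != "classifier"},
                         tmp_path / "r.json")

    def test_directory_path_rejected(self, tmp_path):
        with pytest.raises(OSError):
            write_report(self.MINIMAL, tmp_path)
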