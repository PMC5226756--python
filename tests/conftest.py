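import pytest

from reflexlens.preprocess import StopList, default_stoplist
from reflexlens.synthetic import make_fixture


@pytest.fixture(scope="session")
def stoplist() -> StopList:
    return default_stoplist()


@pytest.fixture(scope="session")
def tiny():
    """6-student hand-checkable corpus plus its ground truth."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def separable():
    """400-student corpus with disjoint per-category vocabularies."""
    return make_fixture("separable")


@pytest.fixture
def mini_stop(tmp_path):
    """A 3-word stoplist written to disk."""
    p = tmp_path / "stop.txt"
    p.write_text("# comment line\nthe\nof\nand\n", encoding="utf-8")
    return p
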