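import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from netphen.synthdata import RELEVANT_SEMANTIC_TYPES
from netphen.textmine import (DocumentAnnotation, TermRecord,
                              VocabularyFilter)


@pytest.fixture
def term_table():
    """Six terms spanning the three vocabularies and two semantic types."""
    def rec(tid, vocabs, sty="Disease or Syndrome"):
        return TermRecord(term_id=tid, source_vocabs=frozenset(vocabs),
                          semantic_type=sty)
    return {
        "t1": rec("t1", {"MeSH"}),
        "t2": rec("t2", {"GO"}, sty="Cell Function"),
        "t3": rec("t3", {"MeSH", "ICD9CM"}),
        "t4": rec("t4", {"ICD9CM"}, sty="Sign or Symptom"),
        "t5": rec("t5", {"MeSH"}, sty="governmental or regulatory activity"),
        "t6": rec("t6", {"GO"}, sty="Cell Function"),
    }


@pytest.fixture
def small_docs():
    return [
        DocumentAnnotation("d1", {"t1": 2, "t2": 1}),
        DocumentAnnotation("d2", {"t1": 1, "t3": 3}),
        DocumentAnnotation("d3", {"t2": 2, "t4": 1, "t5": 1}),
    ]


@pytest.fixture
def sty_filter():
    return VocabularyFilter.by_semantic_types(RELEVANT_SEMANTIC_TYPES)
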