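import pytest

from benchfield.corpus import BenchmarkRanking, Corpus, ToolRecord


@pytest.fixture
def toy_corpus() -> Corpus:
    """Three tools, two benchmarks, two fields; small enough to enumerate."""
    tools = (
        ToolRecord("A", "aligner-a", ("Genetics",)),
        ToolRecord("B", "aligner-b", ("Computer Science",)),
        ToolRecord("C", "aligner-c", ("Genetics", "Computer Science")),
    )
    benchmarks = (
        BenchmarkRanking(
            "bm1", "pub1", "sensitivity", (("A", 1), ("B", 2), ("C", 3))
        ),
        BenchmarkRanking("bm2", "pub1", "MCC", (("B", 1), ("C", 2))),
    )
    return Corpus(tools=tools, benchmarks=benchmarks)


@pytest.fixture
def toy_field_map() -> dict[str, frozenset[str]]:
    return {
        "A": frozenset({"Genetics"}),
        "B": frozenset({"Computer Science"}),
        "C": frozenset({"Genetics", "Computer Science"}),
    }
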