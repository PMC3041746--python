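import pytest

from polysnp.records import Contig, VariantRecord


def rec(contig="c1", start=10, ref="A", var="G", freq=100.0, depth=10,
        genotype="Ogle", end=None):
    return VariantRecord(contig, start, end if end is not None else start,
                         ref, var, freq, depth, genotype)


@pytest.fixture
def truth_table_batch():
    """The eight-record rule-cascade worked example.

    Expected outcome: stage removals (indel 3, depth 1, conservation 2) and
    two survivors.
    """
    return [
        rec(start=10, ref="A", var="G", freq=100.0, depth=5),      # pass
        rec(start=20, ref="A", var="-", freq=100.0, depth=9),      # indel
        rec(start=30, end=31, ref="AT", var="GC", freq=100.0, depth=9),  # indel
        rec(start=40, ref="A", var="N", freq=100.0, depth=9),      # indel stage (N)
        rec(start=50, ref="A", var="G", freq=50.0, depth=50),      # conservation
        rec(start=60, ref="A", var="G", freq=100.0, depth=4),      # depth
        rec(start=70, ref="C", var="T", freq=100.0, depth=30),     # pass
        rec(start=80, ref="G", var="C", freq=99.9, depth=100),     # conservation
    ]


@pytest.fixture
def small_reference():
    return [
        Contig("c1", "ACGT" * 50, "TAM"),
        Contig("c2", "TTGCA" * 40, "TAM"),
    ]
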