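import pandas as pd
import pytest

from methsplice import cd44_like_model
from methsplice.junction_quant import JunctionRecord


@pytest.fixture(scope="session")
def model():
    return cd44_like_model()


@pytest.fixture
def anchor(model):
    return model.exon("C5")


def make_junction(model, donor_exon, acceptor_exon, counts):
    """Junction whose intron runs from donor_exon.end to acceptor_exon.start."""
    d = model.exon(donor_exon)
    a = model.exon(acceptor_exon)
    return JunctionRecord(model.chrom, d.end, a.start, model.strand, dict(counts))


@pytest.fixture
def toy_junctions(model):
    """The hand-computed anchor table: C5->v3 10, C5->v6 5, C5->C16 35 reads
    in one sample; inclusion = 100 * 15/50 = 30%."""
    return [
        make_junction(model, "C5", "v3", {"s1": 10}),
        make_junction(model, "C5", "v6", {"s1": 5}),
        make_junction(model, "C5", "C16", {"s1": 35}),
    ]
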