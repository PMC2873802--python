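import pytest

from lrgkit import fixtures


@pytest.fixture(scope="session")
def col1a1_record():
    return fixtures.make_col1a1_like()


@pytest.fixture(scope="session")
def multi_transcript_record():
    return fixtures.make_multi_transcript_fixture(seed=7)


@pytest.fixture(scope="session")
def small_gene():
    """A compact random gene plus its oracle tables (fast exhaustive tests)."""
    spec = fixtures.GeneModelSpec(seed=11, n_exons=4, exon_length=(24, 60),
                                  intron_length=(15, 60), utr5_length=10,
                                  utr3_length=12)
    return fixtures.make_synthetic_gene(spec)


@pytest.fixture(scope="session")
def reverse_mapped_gene():
    spec = fixtures.GeneModelSpec(seed=5, assembly_strand=-1,
                                  assembly_offset=5000)
    return fixtures.make_synthetic_gene(spec)
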