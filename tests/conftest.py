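import numpy as np
import pytest

from apasnp.io_formats import GeneModel, SnpRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_snp():
    return SnpRecord("rs1", "chr1", 100, "A", "G", {"A": 0.7, "G": 0.3})


@pytest.fixture
def plus_gene():
    return GeneModel(
        gene_id="g1", chrom="chr1", strand="+",
        transcript_intervals=[(50, 250)], cds_end=50,
        utr3_intervals=[(50, 250)], annotated_end=250,
    )
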