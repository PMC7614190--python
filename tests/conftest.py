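import pytest

from bivalentia.genome_model import GeneModel, GenomicInterval, Peak, PeakSet


@pytest.fixture
def gene_plus():
    return GeneModel("g1", "G1", GenomicInterval("chr1", 8000, 12000), "+")


@pytest.fixture
def gene_minus():
    return GeneModel("g2", "G2", GenomicInterval("chr1", 8000, 12000), "-")


@pytest.fixture
def small_peakset():
    return PeakSet(
        [
            Peak("pk1", GenomicInterval("chr1", 1500, 1800)),
            Peak("pk2", GenomicInterval("chr1", 5000, 5100)),
            Peak("pk3", GenomicInterval("chr1", 900, 1001)),
            Peak("pk4", GenomicInterval("chr2", 1000, 2000)),
        ],
        assay="H3K4me3",
    )
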