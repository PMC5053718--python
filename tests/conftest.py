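import numpy as np
import pytest

from clipribo.annotation import GeneClass, TranscriptModel
from clipribo.simulate import SimConfig, Simulator


def make_model(
    exon_blocks,
    cds=None,
    strand="+",
    tid="T1",
    gid="G1",
    cls=GeneClass.MRNA,
    chrom="chr1",
):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        gene_class=cls,
        chrom=chrom,
        strand=strand,
        exon_blocks=tuple(tuple(b) for b in exon_blocks),
        cds_genomic=tuple(cds) if cds else None,
    )


@pytest.fixture
def toy_model():
    """Single exon chr1:0-300, CDS 100-250, plus strand:
    5'UTR 100 / CDS 150 / 3'UTR 50."""
    return make_model([(0, 300)], cds=(100, 250))


@pytest.fixture
def toy_model_minus():
    return make_model([(0, 300)], cds=(100, 250), strand="-")


@pytest.fixture
def two_exon_model():
    """Exons [0,100)+[200,300), CDS 50-250: mature 200, 5'UTR 50 /
    CDS 100 / 3'UTR 50 on the plus strand."""
    return make_model([(0, 100), (200, 300)], cds=(50, 250))


@pytest.fixture(scope="session")
def small_sim():
    """Shared small synthetic dataset (cheap, deterministic)."""
    return Simulator(
        SimConfig(n_genes=300, clip_events=30_000, n_footprints=30_000, seed=7)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)
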