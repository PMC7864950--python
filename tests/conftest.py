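import numpy as np
import pytest
from hypothesis import settings

from nodmap.genome import GeneModel, ReferenceGenome

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def toy_genome() -> ReferenceGenome:
    # chr1 carries a two-exon plus-strand gene: ATG GGA GT..AG GAA TAA
    #   exon1 = ATGGGA (pos 11-16), intron = GTTTTTAG (17-24),
    #   exon2 = GAATAA (25-30); CDS = ATGGGAGAATAA -> MGE*
    chr1 = "ACGTACGTAC" + "ATGGGA" + "GTTTTTAG" + "GAATAA" + "CCGGCCGGCC"
    chr2 = "TTTTGGGGCCCCAAAA"
    return ReferenceGenome([("chr1", chr1), ("chr2", chr2)])


@pytest.fixture()
def toy_gene() -> GeneModel:
    return GeneModel(
        gene_id="toy1",
        chromosome="chr1",
        strand="+",
        exons=[(11, 16), (25, 30)],
        cds=[(11, 16), (25, 30)],
    )


@pytest.fixture()
def toy_gene_minus() -> GeneModel:
    # on the minus strand of a chromosome built as the reverse complement
    # of chr1, the same transcript reads ATGGGAGAATAA
    return GeneModel(
        gene_id="toy1m",
        chromosome="chr1rc",
        strand="-",
        exons=[(11, 16), (25, 30)],
        cds=[(11, 16), (25, 30)],
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
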