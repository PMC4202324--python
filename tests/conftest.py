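import numpy as np
import pytest
from hypothesis import settings

from linecns.genome_io import Feature, FeatureTable, GenomicInterval, SpeciesGenome

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


def random_seq(rng: np.random.Generator, n: int, at: float = 0.5) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_features(species: str, items) -> FeatureTable:
    """items: iterable of (chrom, start, end, strand, type, gene_id)."""
    table = FeatureTable(species)
    for chrom, start, end, strand, ftype, gene_id in items:
        table.add(Feature(GenomicInterval(chrom, start, end, strand), ftype, gene_id))
    return table


@pytest.fixture
def simple_annotation() -> FeatureTable:
    """One gene on chr1 [1000, 3000): 5'UTR [1000,1100), CDS [1100,1500) and
    [2000,2400), intron [1500,2000), 3'UTR [2400,3000)."""
    return make_features(
        "sp",
        [
            ("chr1", 1000, 3000, "+", "gene", "g1"),
            ("chr1", 1000, 1500, "+", "exon", "g1"),
            ("chr1", 2000, 3000, "+", "exon", "g1"),
            ("chr1", 1000, 1100, "+", "five_prime_UTR", "g1"),
            ("chr1", 1100, 1500, "+", "CDS", "g1"),
            ("chr1", 2000, 2400, "+", "CDS", "g1"),
            ("chr1", 2400, 3000, "+", "three_prime_UTR", "g1"),
        ],
    )
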