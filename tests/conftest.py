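import numpy as np
import pytest

from paraloscope import regions
from paraloscope.model import Genome, GenomicInterval
from paraloscope.simcohort import SimLocusSpec, make_locus


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="session")
def identical_locus():
    """Two fully identical 2 kb paralogs (the MQ-0 scenario)."""
    pset, genome = make_locus(SimLocusSpec(length=2000, identity=1.0, seed=3))
    regions.assign_unmasked([pset], [])
    return pset, genome


@pytest.fixture(scope="session")
def divergent_locus():
    """A 1.5 kb pair at 99% identity (~15 SUNs)."""
    pset, genome = make_locus(SimLocusSpec(length=1500, identity=0.99, seed=11))
    regions.assign_unmasked([pset], [])
    return pset, genome


def make_pair_genome(rng, gene_seq: str, pseudo_seq: str, gap: int = 300):
    """A contig holding a gene and its pseudogene with unique flanks."""
    flank = random_dna(rng, 200)
    contig = flank + gene_seq + random_dna(rng, gap) + pseudo_seq + random_dna(rng, 200)
    genome = Genome({"chr1": contig})
    gene_iv = GenomicInterval("chr1", 200, 200 + len(gene_seq))
    ps_iv = GenomicInterval("chr1", 200 + len(gene_seq) + gap,
                            200 + len(gene_seq) + gap + len(pseudo_seq))
    return genome, gene_iv, ps_iv
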