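import numpy as np
import pytest

from crossgs import build_genome, founder_population
from crossgs.genome import GenomeMap, Population


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_map(rng):
    """One chromosome, 20 candidate QTL + 100 candidate SNPs."""
    return build_genome(1, rng, n_qtl_candidates=20, n_snp_candidates=100)


@pytest.fixture
def small_pop(small_map, rng):
    return founder_population(small_map, 30, rng)


def uniform_map(n_loci: int, n_chrom: int = 1,
                mutation_rate: float = 0.0,
                interference: int = 4) -> GenomeMap:
    """Evenly spaced SNP-only map covering [0, 1] on each chromosome."""
    per = n_loci // n_chrom
    pos = np.tile(np.linspace(0.0, 1.0, per), n_chrom)
    chrom = np.repeat(np.arange(n_chrom, dtype=np.int32), per)
    return GenomeMap(n_chromosomes=n_chrom, chrom_length=1.0, chrom=chrom,
                     positions=pos, role=np.ones(per * n_chrom, np.int8),
                     mutation_rate=mutation_rate, interference=interference)


def population_from_haplotypes(hap, **kw) -> Population:
    return Population(haplotypes=np.asarray(hap, np.int8), **kw)
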