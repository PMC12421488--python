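import numpy as np
import pytest

from urbanpurge.genotypes import MISSING, GenotypeMatrix


def make_matrix(
    genotypes,
    pop=None,
    effect=None,
    chrom="chr1",
    ploidy=2,
    pos=None,
    chrom_length=None,
):
    """Small helper to build a GenotypeMatrix from a plain list/array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = g.shape
    if pop is None:
        pop = ["pop0"] * n_ind
    if effect is None:
        effect = ["intergenic"] * n_sites
    if pos is None:
        pos = np.arange(n_sites) * 10
    lengths = {}
    if chrom_length is not None:
        lengths[chrom] = chrom_length
    return GenotypeMatrix(
        genotypes=g,
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(pos),
        effect=np.asarray(effect, dtype=object),
        pop=np.asarray(pop, dtype=object),
        ploidy=ploidy,
        chrom_lengths=lengths,
    )


def random_matrix(rng, n_sites=200, n_ind=12, missing_frac=0.1, two_pops=True):
    """Random diploid matrix with missingness for oracle comparisons."""
    g = rng.integers(0, 3, size=(n_sites, n_ind)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random((n_sites, n_ind)) < missing_frac
        g[mask] = MISSING
    pop = (
        ["urban"] * (n_ind // 2) + ["rural"] * (n_ind - n_ind // 2)
        if two_pops
        else None
    )
    return make_matrix(g, pop=pop, pos=np.sort(rng.choice(10**6, n_sites, replace=False)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
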