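import numpy as np
import pandas as pd
import pytest

from clonepop.genotypes import META_COLUMNS, GenotypeMatrix


def make_matrix(alleles, populations=None, regions=None, coords=None,
                samples=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from an allele table and optional labels."""
    alleles = np.asarray(alleles, dtype=np.int64)
    n, L = alleles.shape
    samples = samples or [f"s{i:03d}" for i in range(n)]
    populations = populations or ["pop0"] * n
    if regions is None:
        regions = [f"reg_{p}" for p in populations]
    if coords is None:
        coords = [(20.0, 100.0, 1000.0)] * n
    meta = pd.DataFrame(
        [(r, p, "habitat", lat, lon, alt)
         for r, p, (lat, lon, alt) in zip(regions, populations, coords)],
        columns=list(META_COLUMNS[1:]),
    )
    meta.index = pd.Index(samples, name="sample_id")
    return GenotypeMatrix(
        samples=samples,
        loci=[f"L{j:02d}" for j in range(L)],
        alleles=alleles,
        metadata=meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_pop_matrix():
    """Two populations in two regions, 4 biallelic loci."""
    alleles = [
        [0, 0, 1, 0], [0, 1, 1, 0], [1, 0, 0, 0], [0, 0, 0, 1],
        [1, 1, 0, 1], [1, 1, 1, 1], [1, 0, 1, 1], [0, 1, 0, 1],
    ]
    pops = ["pa"] * 4 + ["pb"] * 4
    regs = ["ra"] * 4 + ["rb"] * 4
    return make_matrix(alleles, pops, regs)
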