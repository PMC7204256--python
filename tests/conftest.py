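import numpy as np
import pytest

from phenofix import GenotypeMatrix, PhenotypeVector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """60-sample, 4-SNP dataset with a genuine genotype-phenotype link."""
    n = 60
    g = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
    liab = g @ np.array([1.0, 0.8, 0.0, 0.0]) + rng.standard_normal(n)
    y = (liab > np.median(liab)).astype(int)
    return GenotypeMatrix.from_counts(g), PhenotypeVector(y)
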