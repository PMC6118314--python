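import numpy as np
import pytest

import gsdecision as gd


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_univariate_data():
    """A small simulated single-trait dataset at h2 = 0.5 (n=200, p=50)."""
    rng = np.random.default_rng(101)
    X = gd.simulate_founders(200, 50, rng).astype(float)
    beta = rng.normal(0.0, 0.3, 50)
    g = X @ beta
    y = g + rng.normal(0.0, np.sqrt(g.var()), 200)
    return X, y, beta


@pytest.fixture(scope="session")
def small_multitrait_data():
    """Three correlated traits on 180 lines, 250 loci, h2 = 0.5 each."""
    rng = np.random.default_rng(202)
    geno = gd.simulate_founders(180, 250, rng).astype(float)
    eff = gd.sample_effects_multitrait(250, gd.DEFAULT_CORRELATIONS, rng, genotypes=geno)
    tbv = geno @ eff
    h2 = np.full(3, 0.5)
    se2 = gd.calibrate_residual_variance(tbv, h2)
    Y = tbv + rng.standard_normal(tbv.shape) * np.sqrt(se2)
    K = gd.genomic_relationship(geno)
    return geno, tbv, Y, K
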