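import numpy as np
import pytest

from bfscreen.residualize import residualize
from bfscreen.simulate import SyntheticConfig, simulate_replicate


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic replicate for fast unit tests (~150 variants)."""
    config = SyntheticConfig(n_individuals=150, n_genes=30)
    return simulate_replicate(config, seed=7)


@pytest.fixture(scope="session")
def small_response(small_study):
    resid = residualize(
        small_study.pheno.trait, small_study.pheno.covariates.to_numpy()
    )
    return resid.values


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
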