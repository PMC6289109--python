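import numpy as np
import pytest

from pdrank import Sample, fit_density, fixture_suite

GLOBAL_SEED = 20180293  # arbitrary fixed seed for the whole suite


@pytest.fixture(scope="session")
def suite():
    """Canonical sample per shape, moderate size for fast model fits."""
    return fixture_suite(GLOBAL_SEED, n=4000)


@pytest.fixture(scope="session")
def models(suite):
    """One fitted IQR-rule Gaussian model per canonical fixture."""
    return {name: fit_density(s) for name, s in suite.items()}


@pytest.fixture(scope="session")
def big_normal():
    """Large seeded standard-Normal sample for consistency checks."""
    rng = np.random.default_rng(GLOBAL_SEED)
    return Sample(rng.standard_normal(50_000), label="normal-50k")


@pytest.fixture(scope="session")
def big_normal_model(big_normal):
    return fit_density(big_normal)
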