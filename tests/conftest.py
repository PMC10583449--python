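import numpy as np
import pytest

from aqsol import synthetic


@pytest.fixture(scope="session")
def molecules_1000():
    """1000 distinct grammar-generated molecules, max 12 carbons."""
    return synthetic.generate_molecules(1000, max_carbons=12, seed=11)


@pytest.fixture(scope="session")
def planted_records_500(molecules_1000):
    """500-molecule table with the default planted model at noise 0.3."""
    model = synthetic.PlantedModel(noise_sd=0.3, seed=7)
    return synthetic.assign_logS(molecules_1000[:500], model), model


@pytest.fixture(scope="session")
def small_feature_problem():
    """Dense random regression problem for model-level tests."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(120, 6))
    beta = np.array([2.0, -1.0, 0.5, 0.0, 1.5, -0.25])
    y = X @ beta + 0.1 * rng.normal(size=120)
    return X, y
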