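import numpy as np
import pytest

from lncmodnet.synthetic import default_config, generate_dataset, suggested_mr_fraction

# mutual-rank selection fraction matched to the bundled fixture scale:
# sqrt(200 * 800) * fraction just covers a planted block's worst mutual
# rank sqrt(60 * 15) while keeping background leakage small
FIXTURE_MR_FRACTION = suggested_mr_fraction(default_config())


@pytest.fixture(scope="session")
def fixture_mr_fraction():
    return FIXTURE_MR_FRACTION


@pytest.fixture(scope="session")
def planted_dataset():
    """Default three-module synthetic dataset (tumour, normal, clinical, truth)."""
    return generate_dataset(default_config(seed=7))


@pytest.fixture(scope="session")
def planted_config():
    return default_config(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
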