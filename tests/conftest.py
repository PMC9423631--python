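import numpy as np
import pytest

from cognoise import synthetic, targets


@pytest.fixture(scope="session")
def semantic_space():
    """Stock 64-name, 8-category synthetic space."""
    return synthetic.default_space(seed=0)


@pytest.fixture(scope="session")
def mixture(semantic_space):
    return synthetic.default_mixture(semantic_space, seed=0)


@pytest.fixture(scope="session")
def bimodal_1d():
    """Equal-weight modes at +-5 with unit sd: the mode-hopping stress case."""
    return targets.GaussianMixture1D(
        weights=np.array([0.5, 0.5]), means=np.array([-5.0, 5.0]), sds=np.array([1.0, 1.0])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
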