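import numpy as np
import pytest

from silicofem import FixtureSpec, SurrogateParams, fit_atlas, generate_atlas_training


@pytest.fixture(scope="session")
def default_atlas():
    """Atlas fitted to the default 94-femur synthetic training set."""
    rng = np.random.default_rng(42)
    X, meta = generate_atlas_training(FixtureSpec(), rng)
    return fit_atlas(X, feature_meta=meta)


@pytest.fixture(scope="session")
def default_training():
    rng = np.random.default_rng(42)
    return generate_atlas_training(FixtureSpec(), rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def surrogate():
    return SurrogateParams()
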