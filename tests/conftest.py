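import numpy as np
import pytest

from brainfuse import SyntheticFeatureSpec, make_feature_fixture


@pytest.fixture(scope="session")
def feature_fixture():
    """Default planted-structure fixture (4 classes, d=60, 8 informative)."""
    return make_feature_fixture(SyntheticFeatureSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
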