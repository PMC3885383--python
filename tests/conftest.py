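import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_feature_matrix(n_blocks, n_channels=2, block_len=60.0, rng=None,
                        valid=None):
    """Small iid log-normal feature matrix for structural tests."""
    from pibcast.features import FeatureMatrix, feature_names, DEFAULT_BANDS
    if rng is None:
        rng = np.random.default_rng(0)
    names = feature_names(n_channels, DEFAULT_BANDS)
    X = 10.0 ** rng.normal(1.0, 0.3, size=(n_blocks, len(names)))
    if valid is None:
        valid = np.ones(n_blocks, dtype=bool)
    X[~valid] = np.nan
    return FeatureMatrix(np.arange(n_blocks) * block_len, X, names,
                         np.asarray(valid, bool), block_len)
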