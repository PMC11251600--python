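import numpy as np
import pytest

from bimgo.binary_fs import FeatureDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_dataset():
    """60 instances, 4 features; feature 0 separates the classes perfectly,
    the rest are pure noise."""
    gen = np.random.default_rng(7)
    n = 60
    labels = np.repeat([0, 1], n // 2)
    gen.shuffle(labels)
    matrix = gen.standard_normal((n, 4))
    matrix[:, 0] = np.where(labels == 1, 5.0, -5.0) + 0.1 * gen.standard_normal(n)
    return FeatureDataset(
        matrix=matrix,
        labels=labels,
        feature_names=[f"x{j}" for j in range(4)],
        missing_mask=np.zeros((n, 4), dtype=bool),
        positive_class=1,
    )
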