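import numpy as np
import pytest

from dcthac import build_feature_matrix, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed-class synthetic dataset for plumbing tests."""
    return generate_dataset(
        {"ARR": 4, "CHF": 3, "NSR": 3}, n_samples=1024, fs=128, seed=11
    )


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return build_feature_matrix(small_dataset, num_coefficients=64, hac_fraction=0.5)


@pytest.fixture(scope="session")
def desk_scale_features():
    """The shipped desk-scale ARR-vs-NSR dataset: 96/36 records of 8192
    samples at 128 Hz, M = 256, HAC width 128, master seed 1."""
    ds = generate_dataset({"ARR": 96, "NSR": 36}, n_samples=8192, fs=128, seed=1)
    return build_feature_matrix(ds, num_coefficients=256, hac_fraction=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
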