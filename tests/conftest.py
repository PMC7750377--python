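import numpy as np
import pytest

from cdboost import (
    EmbeddingConfig,
    SyntheticSpec,
    extract_cd_features,
    generate_eeg_dataset,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_eeg_records():
    """Six small two-class records (8 channels x 400 samples), session-cached."""
    spec = SyntheticSpec(
        n_records_per_class=3, n_channels=8, n_samples=400, seed=7
    )
    return generate_eeg_dataset(spec)


@pytest.fixture(scope="session")
def small_cd_matrix(small_eeg_records):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return extract_cd_features(small_eeg_records, EmbeddingConfig())


@pytest.fixture(scope="session")
def medium_cd_matrix():
    """Two-class CD matrix big enough for selection/CV tests (16ch x 640)."""
    import warnings

    spec = SyntheticSpec(
        n_records_per_class=12, n_channels=16, n_samples=640, seed=11
    )
    records = generate_eeg_dataset(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return extract_cd_features(records, EmbeddingConfig())
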