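import numpy as np
import pytest

import typoclust as tc


@pytest.fixture
def rng():
    return np.random.default_rng(20240523)


@pytest.fixture
def std_sample(rng):
    """Random standardized 60 x 4 sample."""
    return tc.standardize(tc.DataMatrix(rng.normal(size=(60, 4))))


@pytest.fixture
def two_blobs(rng):
    """Two tight, far-separated 2-D blobs of 25 cases each."""
    X = np.vstack(
        [rng.normal(0, 0.3, (25, 2)), rng.normal(6, 0.3, (25, 2))]
    )
    truth = np.repeat([1, 2], 25)
    return tc.DataMatrix(X), tc.Partition(truth, k=2)


@pytest.fixture(scope="session")
def typology7():
    """The default seeded 7-type synthetic sample with true labels."""
    data, part = tc.generate_typology(tc.TypologySpec(seed=20240523))
    return tc.standardize(data), part
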