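import numpy as np
import pytest

from milsom import Codebook, Dataset, SOMGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    return Dataset(rng.normal(size=(40, 3)))


def make_codebook(weights, rows, cols, topology="rectangular"):
    return Codebook(np.asarray(weights, dtype=float), SOMGrid(rows, cols, topology))


@pytest.fixture
def random_codebook(rng):
    return make_codebook(rng.normal(size=(12, 3)), 3, 4)
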