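import numpy as np
import pytest

import pwmforge as pf


@pytest.fixture(scope="session")
def trained_model():
    """Potential trained on the default synthetic corpus (seed 0)."""
    corpus = pf.make_training_corpus(seed=0)
    return pf.train_potential(corpus)


@pytest.fixture(scope="session")
def planted_tc():
    """Ten-position planted reader complex with known preferences."""
    return pf.build_planted_complex("ACGTTACGGA")


@pytest.fixture(scope="session")
def small_corpus():
    """A small corpus for cheap structural tests (not for recovery claims)."""
    return pf.make_training_corpus(n_complexes=5, seed=3, length=6)


def random_rotation(seed):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
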