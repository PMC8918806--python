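import numpy as np
import pytest

import vasquant as vq


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_tree():
    """A compact bifurcating tree phantom shared by read-only tests."""
    spec = vq.PhantomSpec(
        shape=(64, 160, 128),
        radius=6.0,
        n_bifurcations=3,
        segment_length=(25.0, 40.0),
        seed=4,
    )
    return vq.generate_tree_phantom(spec) + (spec,)


@pytest.fixture(scope="session")
def symmetric_phantom():
    spec = vq.PhantomSpec(
        shape=(64, 160, 128),
        radius=6.0,
        n_bifurcations=3,
        segment_length=(20.0, 30.0),
        seed=4,
    )
    return vq.generate_symmetric_phantom(spec) + (spec,)
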