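import numpy as np
import pytest

from stackmae.synthetic import make_instances


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_labels():
    rng = np.random.default_rng(11)
    return make_instances((8, 48, 48), n_objects=10, rng=rng)


@pytest.fixture(scope="session")
def mito_labels():
    """Mitochondria-like fixture: isolated ellipsoids with a background gap."""
    rng = np.random.default_rng(13)
    return make_instances(
        (12, 96, 96),
        n_objects=12,
        min_radius=6,
        max_radius=12,
        rng=rng,
        tube_fraction=0.0,
        gap=2,
    )
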