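import numpy as np
import pytest

import hmrfclust as hc


@pytest.fixture(scope="session")
def small_reference():
    """Spatially coherent 3-cluster reference on a small grid."""
    return hc.make_synthetic_reference(
        (6, 6, 4), n_clusters=3, n_genes=14, seed=11, theta_spec="separated",
        delta=0.5, min_region_size=20,
    )


@pytest.fixture(scope="session")
def small_data(small_reference):
    return hc.simulate_from_reference(small_reference, seed=12)


@pytest.fixture()
def line_graph():
    """Three voxels in a row: 0 - 1 - 2."""
    return hc.build_graph(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]]))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
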