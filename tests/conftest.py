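import numpy as np
import pytest

import hubgrad as hg


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions shared across module tests."""
    return hg.CohortConfig(
        n_nodes=80,
        n_subjects_per_group={"CN_Aneg": 20, "CN_Apos": 10, "CI": 15},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return hg.generate_cohort(small_config)


@pytest.fixture(scope="session")
def parcellation():
    return hg.make_parcellation(100, seed=1)


@pytest.fixture(scope="session")
def fc_connectome(parcellation):
    cfg = hg.CohortConfig(seed=1)
    return hg.make_connectome(parcellation, "FC", "CN_Aneg", cfg, 42)


@pytest.fixture(scope="session")
def sc_connectome(parcellation):
    cfg = hg.CohortConfig(seed=1)
    return hg.make_connectome(parcellation, "SC", "CN_Aneg", cfg, 43)


def random_symmetric_affinity(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a
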