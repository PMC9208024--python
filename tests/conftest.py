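import numpy as np
import pytest

from scfc.fc import THETA, FrequencyBand
from scfc.synth import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort: few subjects, few nodes, short recordings."""
    return CohortConfig(
        n_hc=6,
        n_cp=6,
        n_ci=5,
        n_nodes=16,
        n_epochs=2,
        epoch_samples=2048,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, mode="fc")


@pytest.fixture(scope="session")
def small_ts_cohort(small_config):
    return generate_cohort(small_config, mode="both")


def random_connectome(rng, n_nodes=10, absent_fraction=0.3):
    """Ad-hoc valid connectome for oracle comparisons."""
    from scfc.sc import StructuralConnectome

    iu = np.triu_indices(n_nodes, k=1)
    lengths = rng.uniform(5.0, 200.0, size=iu[0].size)
    fa = rng.uniform(0.05, 0.9, size=iu[0].size)
    absent = rng.random(iu[0].size) < absent_fraction
    fa[absent] = 0.0
    L = np.zeros((n_nodes, n_nodes))
    F = np.zeros((n_nodes, n_nodes))
    L[iu] = lengths
    F[iu] = fa
    return StructuralConnectome(
        fa=F + F.T, lengths=L + L.T, node_labels=[f"n{i}" for i in range(n_nodes)]
    )


@pytest.fixture
def make_connectome(rng):
    return lambda **kw: random_connectome(rng, **kw)
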