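import numpy as np
import pytest
from hypothesis import settings

import sicenet as sn

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def partition42():
    return sn.aal42_partition()


@pytest.fixture(scope="session")
def partition10():
    return sn.toy_partition(10)


@pytest.fixture(scope="session")
def truth10(partition10):
    """Single-group sparse ground truth on 10 regions."""
    return sn.make_group_precision(
        partition10,
        intra_edge_prob=0.5,
        inter_edge_prob=0.1,
        seed=5,
        groups=("CN",),
    )


@pytest.fixture(scope="session")
def identity_truth():
    """Standard-normal ground truth (Theta = I, mu = 0) on 4 regions."""
    part = sn.toy_partition(4)
    return sn.GroundTruth(
        partition=part,
        theta_by_group={"CN": np.eye(4)},
        mu_by_group={"CN": np.zeros(4)},
        edge_support={"CN": frozenset()},
    )


def random_adjacency(rng: np.random.Generator, n: int, q: float = 0.3) -> np.ndarray:
    """Erdos-Renyi style symmetric 0/1 adjacency with zero diagonal."""
    a = (rng.random((n, n)) < q).astype(int)
    a = np.triu(a, k=1)
    return a + a.T
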