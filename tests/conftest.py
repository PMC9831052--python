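import numpy as np
import pytest

from netshy import ProfileMatrix, WeightedNetwork, generate_er_network


@pytest.fixture
def path3() -> WeightedNetwork:
    """3-node path with weights 0.2 (v0-v1) and 0.7 (v1-v2)."""
    A = np.array([[0.0, 0.2, 0.0], [0.2, 0.0, 0.7], [0.0, 0.7, 0.0]])
    return WeightedNetwork(node_ids=("v0", "v1", "v2"), adjacency=A)


@pytest.fixture
def star5() -> WeightedNetwork:
    """5-node star centered on v0, unit weights."""
    A = np.zeros((5, 5))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    return WeightedNetwork(node_ids=tuple(f"v{k}" for k in range(5)), adjacency=A)


@pytest.fixture
def random_net() -> WeightedNetwork:
    return generate_er_network(8, 0.5, seed=42)


def make_profiles(n: int, p: int, seed: int = 0) -> ProfileMatrix:
    rng = np.random.default_rng(seed)
    return ProfileMatrix(
        subject_ids=tuple(f"s{i}" for i in range(n)),
        feature_ids=tuple(f"v{j}" for j in range(p)),
        values=rng.standard_normal((n, p)),
    )


@pytest.fixture
def profiles_8x5() -> ProfileMatrix:
    return make_profiles(8, 5, seed=3)
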