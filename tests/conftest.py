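import numpy as np
import pytest

from lncdra import (AssociationMatrix, AssociationRecord, TrainConfig,
                    build_matrix)


@pytest.fixture
def tiny_matrix() -> AssociationMatrix:
    """The 3x2 worked example: profiles (1,0), (0,1), (1,1)."""
    return AssociationMatrix(
        np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        ["L1", "L2", "L3"], ["D1", "D2"])


@pytest.fixture
def small_config() -> TrainConfig:
    """A scaled-down config for fast training tests."""
    return TrainConfig(epochs=20, embedding_size=8, gcn_hidden=8, heads=2,
                       learning_rate=1e-2, seed=0, knn=None)


def random_association(rng: np.random.Generator, m: int, n: int,
                       density: float = 0.4) -> AssociationMatrix:
    """Random binary matrix with at least one positive."""
    while True:
        A = (rng.random((m, n)) < density).astype(float)
        if A.sum() >= 1:
            break
    return AssociationMatrix(A, [f"L{i}" for i in range(m)],
                             [f"D{j}" for j in range(n)])
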