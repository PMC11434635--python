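import numpy as np
import pytest

from ahp_refine import PairwiseComparisonMatrix, validate_matrix
from ahp_refine.datasets import (
    client1_initial,
    client1_refined,
    client2_initial,
    client2_refined,
)


@pytest.fixture
def c1_initial() -> PairwiseComparisonMatrix:
    return client1_initial()


@pytest.fixture
def c1_refined() -> PairwiseComparisonMatrix:
    return client1_refined()


@pytest.fixture
def c2_initial() -> PairwiseComparisonMatrix:
    return client2_initial()


@pytest.fixture
def c2_refined() -> PairwiseComparisonMatrix:
    return client2_refined()


@pytest.fixture
def all_client_matrices(c1_initial, c1_refined, c2_initial, c2_refined):
    return [c1_initial, c1_refined, c2_initial, c2_refined]


def random_reciprocal(n: int, rng: np.random.Generator) -> PairwiseComparisonMatrix:
    """Random positive reciprocal matrix with log-uniform judgments in [1/9, 9]."""
    a = np.eye(n)
    iu, ju = np.triu_indices(n, k=1)
    vals = np.exp(rng.uniform(np.log(1 / 9), np.log(9), size=len(iu)))
    a[iu, ju] = vals
    a[ju, iu] = 1.0 / vals
    return validate_matrix(a)
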