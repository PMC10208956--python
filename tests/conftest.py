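import numpy as np
import pytest

from epitopescan import (
    ScoringMatrix,
    make_ground_truth,
    simulate_pssl_plate,
)


@pytest.fixture
def flat_matrix():
    """All 200 entries equal 2.0: every decamer scores 20, percent 100."""
    return ScoringMatrix(np.full((10, 20), 2.0))


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(42)
    return ScoringMatrix(rng.normal(2.0, 0.8, size=(10, 20)))


@pytest.fixture
def truth():
    return make_ground_truth(1)


@pytest.fixture
def noiseless_truth():
    return make_ground_truth(1, noise_cv=0.0)


@pytest.fixture
def noiseless_plate(noiseless_truth):
    return simulate_pssl_plate(noiseless_truth, n_experiments=3, seed=2)


def random_decamers(n, seed=0):
    from epitopescan.residues import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    return [
        "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 10)) for _ in range(n)
    ]
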