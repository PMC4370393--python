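import numpy as np
import pytest

from dompop import BinaryMarkerMatrix, paper_like_dataset, simulate


@pytest.fixture(scope="session")
def paper_like():
    """A 172 x 180 dataset shaped like the study, with known truth."""
    return paper_like_dataset(seed=20150323)


@pytest.fixture(scope="session")
def small_sim():
    """Moderately differentiated small dataset for fast estimator checks."""
    return simulate(4, 12, 40, theta=0.2, f=0.1, seed=7)


@pytest.fixture
def toy_matrix():
    """3 populations x 4 individuals x 5 loci, fully scored, handmade."""
    calls = np.array(
        [
            [1, 1, 0, 1, 0],
            [1, 0, 0, 1, 0],
            [1, 1, 0, 1, 1],
            [1, 0, 1, 1, 0],
            [0, 1, 1, 0, 0],
            [0, 1, 1, 0, 1],
            [0, 0, 1, 0, 1],
            [0, 1, 1, 1, 1],
            [1, 1, 1, 0, 0],
            [1, 1, 0, 0, 1],
            [0, 1, 1, 0, 0],
            [1, 1, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    return BinaryMarkerMatrix(
        calls=calls,
        individual_ids=[f"i{n}" for n in range(12)],
        populations=["A"] * 4 + ["B"] * 4 + ["C"] * 4,
        locus_ids=[f"L{n}" for n in range(5)],
    )


def random_matrix(rng, n_pops, n_per_pop, n_loci, missing_rate=0.0):
    """Random valid matrix for property tests (at least 2 inds/pop)."""
    n = n_pops * n_per_pop
    calls = rng.integers(0, 2, size=(n, n_loci)).astype(np.int8)
    if missing_rate:
        mask = rng.random((n, n_loci)) < missing_rate
        calls[mask] = -1
    return BinaryMarkerMatrix(
        calls=calls,
        individual_ids=[f"ind{j}" for j in range(n)],
        populations=[f"P{k}" for k in range(n_pops) for _ in range(n_per_pop)],
        locus_ids=[f"L{j}" for j in range(n_loci)],
    )
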