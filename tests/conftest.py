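import numpy as np
import pytest

from lpfuse.data_io import InteractionTable
from lpfuse.similarity import SimilarityMatrix


@pytest.fixture
def toy_interactions() -> InteractionTable:
    return InteractionTable.from_pairs(
        [("L1", "P1"), ("L1", "P2"), ("L2", "P1"), ("L2", "P3"), ("L3", "P2"), ("L3", "P3")]
    )


def random_similarity(n: int, rng: np.random.Generator, index=None) -> SimilarityMatrix:
    """A valid random similarity matrix: symmetric, in [0,1], unit diagonal."""
    raw = rng.random((n, n))
    sym = (raw + raw.T) / 2.0
    np.fill_diagonal(sym, 1.0)
    idx = index if index is not None else tuple(f"P{i}" for i in range(n))
    return SimilarityMatrix(index=idx, values=sym).validate()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
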