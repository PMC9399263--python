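import numpy as np
import pytest
from hypothesis import settings

from secom import CountTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_table() -> CountTable:
    """3 taxa x 2 samples with one zero per the worked examples."""
    return CountTable(
        counts=np.array([[5, 0], [2, 1], [3, 0]]),
        taxon_ids=["T1", "T2", "T3"],
        sample_ids=["S1", "S2"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_count_table(rng: np.random.Generator, d: int = 12, n: int = 9,
                       zero_frac: float = 0.25) -> CountTable:
    counts = rng.poisson(30.0, size=(d, n)) + 1
    counts[rng.random((d, n)) < zero_frac] = 0
    # keep every taxon and sample observed at least once
    for j in range(d):
        if counts[j].sum() == 0:
            counts[j, rng.integers(n)] = 7
    for i in range(n):
        if counts[:, i].sum() == 0:
            counts[rng.integers(d), i] = 7
    return CountTable(
        counts=counts,
        taxon_ids=[f"T{j}" for j in range(d)],
        sample_ids=[f"S{i}" for i in range(n)],
    )


@pytest.fixture
def random_table(rng) -> CountTable:
    return random_count_table(rng)
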