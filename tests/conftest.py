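import numpy as np
import pytest

from chromstate import GenomeLayout, IntervalSet


@pytest.fixture
def small_layout() -> GenomeLayout:
    """Two tiny chromosomes, 200 bp bins; chr2 has a truncated final bin."""
    return GenomeLayout(("chr1", "chr2"), (2000, 1100), 200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


def random_interval_set(
    rng: np.random.Generator,
    n_intervals: int = 12,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    span: int = 3000,
    max_len: int = 400,
) -> IntervalSet:
    """Small random interval set confined to a few kb per chromosome."""
    ivs = []
    for _ in range(n_intervals):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span - 1))
        end = start + 1 + int(rng.integers(max_len))
        ivs.append((chrom, start, end))
    return IntervalSet.from_tuples(ivs)
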