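import numpy as np
import pytest

from nadkit import (
    BinGrid,
    GenomeAssembly,
    Interval,
    SimulationConfig,
    make_bins,
)
from nadkit.simulate import simulate_bin_counts, simulate_truth


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def truth(default_config):
    return simulate_truth(default_config)


@pytest.fixture(scope="session")
def counts(truth, default_config):
    return simulate_bin_counts(truth, default_config)


@pytest.fixture
def small_assembly() -> GenomeAssembly:
    return GenomeAssembly({"chrA": 500_000, "chrB": 300_000})


@pytest.fixture
def small_grid(small_assembly) -> BinGrid:
    return make_bins(small_assembly, 100_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chroms=("chrA", "chrB"), max_pos=10_000, max_len=400):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(Interval(chrom, start, start + length))
    return out


def planted_nad_mask(truth, grid) -> np.ndarray:
    mask = np.zeros(grid.n_bins, dtype=bool)
    for iv in truth.nads:
        first = grid.bin_index(iv.chrom, iv.start)
        last = grid.bin_index(iv.chrom, iv.end - 1)
        mask[first : last + 1] = True
    return mask
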