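import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from replitempo.core import BinIndex, FractionStack, Heatmap

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

B = 50_000


@pytest.fixture
def small_index():
    """One 10-bin chromosome."""
    return BinIndex.from_chrom_sizes({"chr1": 10 * B}, B)


@pytest.fixture
def two_chrom_index():
    return BinIndex.from_chrom_sizes({"chr1": 6 * B, "chr2": 4 * B}, B)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def random_heatmap(index, rng, stage="normalized", mask_frac=0.0):
    mat = rng.uniform(0, 10, size=(16, index.n_bins))
    mask = rng.random(index.n_bins) < mask_frac
    mat[:, mask] = 0.0
    if stage == "normalized":
        sums = mat.sum(axis=0)
        ok = ~mask & (sums > 0)
        mat[:, ok] = mat[:, ok] / sums[ok] * 100.0
        mask = ~ok
    return Heatmap(index, mat, mask, stage)


@pytest.fixture
def uniform_stack(small_index):
    counts = np.full((16, small_index.n_bins), 100.0)
    g1 = np.full(small_index.n_bins, 100.0)
    return FractionStack(small_index, counts, g1)
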