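import numpy as np
import pandas as pd
import pytest

from tomo3d import (
    SectionCountTable,
    SimulationConfig,
    VolumeMask,
    make_dataset,
    normalize_by_spikein,
    reconstruct_all,
)
from tomo3d._axes import section_labels


def make_table(plane, gene_counts, spike_counts):
    """Small count table from dicts of row -> per-section counts."""
    n = len(next(iter(gene_counts.values())))
    cols = section_labels(n)
    return SectionCountTable(
        plane=plane,
        counts=pd.DataFrame(gene_counts, index=cols).T,
        spikeins=pd.DataFrame(spike_counts, index=cols).T,
    )


def random_mask(rng, max_side=6, min_voxels=8):
    """A random connected-ish boolean mask for oracle comparisons."""
    while True:
        shape = tuple(int(rng.integers(3, max_side + 1)) for _ in range(3))
        grid = rng.random(shape) < rng.uniform(0.3, 0.9)
        if grid.sum() >= min_voxels and np.ptp(grid[grid].astype(int)) == 0:
            return VolumeMask(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def cuboid_mask():
    return VolumeMask(np.ones((5, 6, 7), dtype=bool))


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless phantom dataset on a small grid, shared across tests."""
    config = SimulationConfig(shape=(12, 13, 14), noise_model="none", seed=11)
    truth, tables = make_dataset(
        config, {"blob": 3, "midline_stripe": 1, "salt_and_pepper": 2, "uniform": 1}
    )
    return config, truth, tables


@pytest.fixture(scope="session")
def small_model(small_phantom):
    """IPF reconstruction of the small noiseless phantom."""
    _, truth, tables = small_phantom
    profiles = {pl: normalize_by_spikein(tb)[0] for pl, tb in tables.items()}
    model = reconstruct_all(truth.mask, profiles)
    return truth, model
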