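import numpy as np
import pytest

from dropkit.records import Dataset
from dropkit.simulate import SimulationConfig, simulate_dataset
from dropkit.umi_distribution import estimate_umi_distribution


def make_dataset(rows, umi_length=None):
    """Build a Dataset from (cb, umi, gene, reads[, qual or qual-vector]) tuples."""
    cb, umi, gene, reads, quals = [], [], [], [], []
    for row in rows:
        cb.append(row[0])
        umi.append(row[1])
        gene.append(row[2])
        reads.append(row[3])
        L = len(row[1])
        if len(row) > 4:
            q = row[4]
            quals.append([q] * L if np.isscalar(q) else list(q))
        else:
            quals.append([35.0] * L)
    if umi_length is None:
        umi_length = len(umi[0])
    return Dataset.from_arrays(cb, umi, gene, reads, np.array(quals), umi_length=umi_length)


@pytest.fixture(scope="session")
def saturated():
    """The default simulated library: 6-base UMIs, 1% per-read error rate,
    skewed pool, saturated top genes.  Shared across tests for speed."""
    data, truth = simulate_dataset(SimulationConfig(seed=1))
    return data, truth


@pytest.fixture(scope="session")
def saturated_dist(saturated):
    data, _ = saturated
    return estimate_umi_distribution(data)


@pytest.fixture(scope="session")
def quality_scale():
    """Larger, shallow library for cell-quality tests (many cells, small
    per-cell depth, no sequence errors)."""
    cfg = SimulationConfig(
        seed=11,
        n_cells=150,
        n_background=1500,
        cell_molecules_mean=300,
        background_molecules_mean=15,
        umi_error_rate=0.0,
        cb_error_cell_fraction=0.0,
    )
    return simulate_dataset(cfg)
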