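import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from connectomaze.connectome import BrainGraph


def random_brain_graph(n_nodes: int, seed: int, p_edge: float = 0.5) -> BrainGraph:
    """Random weighted undirected graph with max edge weight exactly 1."""
    rng = np.random.default_rng(seed)
    W = np.zeros((n_nodes, n_nodes))
    iu, ju = np.triu_indices(n_nodes, 1)
    mask = rng.random(iu.size) < p_edge
    if not mask.any():
        mask[rng.integers(iu.size)] = True
    w = rng.uniform(0.05, 1.0, size=mask.sum())
    w[rng.integers(w.size)] = 1.0  # pin the normalization contract
    W[iu[mask], ju[mask]] = w
    W += W.T
    return BrainGraph(weights=W, roi_labels=[f"n{i}" for i in range(n_nodes)],
                      density=float(mask.mean()))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_series():
    """10-ROI, 200-volume noiseless-block series for quick connectome tests."""
    from connectomaze.synth import TimeSeriesSimConfig, gen_roi_timeseries

    cfg = TimeSeriesSimConfig(
        n_rois=10, n_volumes=200, dt=2.0,
        block_structure=[(list(range(5)), 0.6), (list(range(5, 10)), 0.3)],
        drift_amplitude=0.2, nuisance_amplitude=0.1, noise_sd=0.2, rng_seed=7,
    )
    return gen_roi_timeseries(cfg)
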