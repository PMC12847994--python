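import numpy as np
import pytest

from ryrflux.simulate import (
    NoiseModel,
    NPCSimConfig,
    VisitModel,
    make_npc_ensemble,
)


@pytest.fixture(scope="session")
def clean_npc():
    """One fully labeled, noise-free pore at identity pose: 32 sites, 32 locs."""
    cfg = NPCSimConfig(
        n_npcs=1,
        p_le=1.0,
        max_tilt_deg=0.0,
        center_jitter=0.0,
        noise=NoiseModel(sigma_xyz=(0.0, 0.0, 0.0)),
        visits=VisitModel(law="fixed", mean_visits=1),
        seed=1,
    )
    gt, table = make_npc_ensemble(cfg)
    return cfg, gt, table


@pytest.fixture(scope="session")
def noisy_npc_field():
    """Medium field used by several reduction / assay tests (p_le=0.6, sigma=2)."""
    cfg = NPCSimConfig(n_npcs=40, p_le=0.6, seed=42)
    gt, table = make_npc_ensemble(cfg)
    return cfg, gt, table


def connected_component_labels(points: np.ndarray, eps: float) -> np.ndarray:
    """Brute-force O(n^2) eps-graph connected components (oracle)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import cdist

    adj = cdist(points, points) <= eps
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Whether two labelings induce the same partition."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        return False
    pairs = {}
    for x, y in zip(a, b):
        if x in pairs and pairs[x] != y:
            return False
        pairs[x] = y
    return len(set(pairs.values())) == len(pairs)
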