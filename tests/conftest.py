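from __future__ import annotations

import numpy as np
import pytest

from percolome.core import ConnectivityMatrix
from percolome.preprocess import group_average, normalize, threshold_proportional
from percolome.synthetic import CohortConfig, generate_cohort


def make_matrix(w, state: str = "thresholded", **kwargs) -> ConnectivityMatrix:
    w = np.asarray(w, dtype=float)
    labels = kwargs.pop("labels", tuple(f"R{i}" for i in range(w.shape[0])))
    return ConnectivityMatrix(weights=w, labels=labels, state=state, **kwargs)


def from_edges(n: int, edges, state: str = "thresholded") -> ConnectivityMatrix:
    """Build a matrix from (i, j) or (i, j, weight) tuples."""
    w = np.zeros((n, n))
    for e in edges:
        i, j, *rest = e
        w[i, j] = w[j, i] = rest[0] if rest else 1.0
    return make_matrix(w, state=state)


@pytest.fixture
def star5() -> ConnectivityMatrix:
    """K1,4: node 0 is the hub."""
    return from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def barbell7() -> ConnectivityMatrix:
    """Two triangles {0,1,2} and {4,5,6} joined through bridge node 3."""
    edges = [(0, 1), (0, 2), (1, 2), (4, 5), (4, 6), (5, 6), (2, 3), (3, 4)]
    return from_edges(7, edges)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort, shared across tests (generation is fast)."""
    cfg = CohortConfig(seed=0)
    control, disease, atlas = generate_cohort(cfg)
    return cfg, control, disease, atlas


@pytest.fixture(scope="session")
def control_average(default_cohort) -> ConnectivityMatrix:
    _, control, _, _ = default_cohort
    return threshold_proportional(normalize(group_average(control)), 0.10)
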