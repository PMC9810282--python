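"""Collective influence scoring for optimal-percolation node ranking.

CI_l(i) = (k_i - 1) * sum over nodes j on the boundary of the ball of hop
radius l around i of (k_j - 1).  High-CI nodes are those whose removal most
effectively fragments the giant component; ranking by CI is the basis of
the optimal-percolation attack scheme.  The score is purely combinatorial:
hop distances on the binary topology are used even for weighted networks.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .core import ConnectivityMatrix, ConnectomeError, require_state


def collective_influence_scores(m: ConnectivityMatrix, ell: int = 2) -> np.ndarray:
    """Per-node CI_l values on the binary topology of ``m``.

    Nodes of degree <= 1 always score 0 (the ``k - 1`` factor vanishes);
    so do nodes whose radius-``ell`` ball boundary is empty.
    """
    require_state(m, "thresholded", "binarized")
    if ell < 1:
        raise ConnectomeError(f"ball radius ell must be >= 1, got {ell}")
    adj = (m.weights != 0).astype(np.int8)
    degree = adj.sum(axis=1).astype(np.int64)
    hops = dijkstra(csr_matrix(adj), directed=False, unweighted=True)
    boundary = hops == ell
    # sum of (k_j - 1) over boundary nodes, per source node
    excess = (degree - 1).astype(float)
    boundary_sum = boundary @ excess
    return (degree - 1) * boundary_sum
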