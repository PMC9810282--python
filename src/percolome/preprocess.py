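"""Group averaging, normalization, proportional thresholding and binarization.

The canonical group-level pipeline is: average raw signed correlation
matrices within each group, clip negatives and rescale to a unit maximum,
then keep the top fraction of edges so every network is compared at the
same graph density (default 10%).  For a 90-region parcellation this keeps
E = round(0.10 * 4005) = 401 edges, i.e. density 0.1001 and mean degree
2E/n = 8.911.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .core import (
    ConnectivityMatrix,
    ConnectomeError,
    check_aligned,
    require_state,
)


def n_pairs(n: int) -> int:
    """Number of unique off-diagonal region pairs, n(n-1)/2."""
    return n * (n - 1) // 2


def edge_budget(density: float, n: int) -> int:
    """Edges retained at a proportional density: round half away from zero.

    Half-away-from-zero (not banker's) rounding matters at exact halves:
    with n=90 and density 0.10 the target 400.5 rounds to 401.
    """
    target = density * n_pairs(n)
    return int(math.floor(target + 0.5))


def group_average(ms: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of raw subject matrices sharing a label set."""
    check_aligned(ms)
    for m in ms:
        require_state(m, "raw")
    mean = np.mean([m.weights for m in ms], axis=0)
    groups = {m.group for m in ms}
    return ConnectivityMatrix(
        weights=mean,
        labels=ms[0].labels,
        subject_id=f"group-average({len(ms)})",
        group=groups.pop() if len(groups) == 1 else "control",
        state="raw",
    )


def normalize(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Clip negative correlations to zero and rescale so the maximum is 1.

    An all-zero (or all-nonpositive) matrix stays all-zero.  Any strictly
    monotone rescaling yields the same thresholded topology; division by the
    maximum is chosen so downstream weighted quantifiers see weights in
    [0, 1].
    """
    require_state(m, "raw")
    w = np.clip(m.weights, 0.0, None)
    peak = w.max()
    if peak > 0:
        w = w / peak
    return m.with_weights(w, state="normalized")


def threshold_proportional(
    m: ConnectivityMatrix, density: float = 0.10
) -> ConnectivityMatrix:
    """Keep the top-weighted fraction of edges; zero the rest.

    Retains ``E = round_half_away_from_zero(density * n(n-1)/2)`` edges
    (fewer if the matrix has fewer positive entries).  Ties at the cut
    weight are broken by ascending (i, j) index order for cross-platform
    determinism.
    """
    require_state(m, "normalized")
    if not 0.0 < density <= 1.0:
        raise ConnectomeError(f"density must be in (0, 1], got {density}")
    n = m.n
    budget = edge_budget(density, n)
    iu = np.triu_indices(n, k=1)
    weights = m.weights[iu]
    # stable sort on descending weight preserves ascending (i, j) among ties
    order = np.argsort(-weights, kind="stable")
    keep = order[:budget]
    keep = keep[weights[keep] > 0]
    out = np.zeros_like(m.weights)
    rows, cols = iu[0][keep], iu[1][keep]
    out[rows, cols] = weights[keep]
    out[cols, rows] = weights[keep]
    return m.with_weights(out, state="thresholded")


def binarize(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Map surviving weights to 1."""
    require_state(m, "thresholded")
    return m.with_weights((m.weights != 0).astype(float), state="binarized")


def binary_subtract(
    a: ConnectivityMatrix, b: ConnectivityMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Signed difference of two binarized networks, plus their shared mask.

    Returns ``(diff, shared)`` where ``diff = a - b`` has entries in
    {-1, 0, 1} (+1 = edge only in ``a``, -1 = only in ``b``, 0 = shared or
    absent) and ``shared = a * b`` marks edges present in both.  The signed
    matrix is the BrainNet Viewer input for visualizing group edge
    differences.
    """
    require_state(a, "binarized")
    require_state(b, "binarized")
    check_aligned([a, b])
    return a.weights - b.weights, a.weights * b.weights
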