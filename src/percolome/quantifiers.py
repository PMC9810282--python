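"""Weighted global and nodal graph quantifiers for thresholded connectomes.

Conventions follow common practice for weighted brain networks:

* edge length for shortest paths is the reciprocal of the weight
  (strong correlations are short);
* characteristic path length (CPL), global efficiency, radius and diameter
  average over *finite* off-diagonal distances only — thresholding and node
  attacks fragment the network, and unreachable pairs are omitted rather
  than scored as infinite (or, for efficiency, as zero);
* betweenness is unnormalized raw path counts with endpoints excluded;
* clustering is the Onnela geometric-mean triangle formula with weights
  rescaled by the network maximum;
* community structure is the best-modularity Louvain partition over
  seeded restarts, and the participation coefficient is computed against
  that partition.

Every weighted quantifier reduces to its binary counterpart when all
surviving weights are 1.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .core import ConnectivityMatrix, ConnectomeError, require_state

NODAL_METRICS = (
    "degree",
    "strength",
    "betweenness",
    "eigenvector",
    "clustering",
    "local_efficiency",
    "participation",
)


# ---------------------------------------------------------------------------
# distances


def shortest_path_lengths(m: ConnectivityMatrix) -> np.ndarray:
    """All-pairs shortest path lengths with edge length = 1/weight.

    Unreachable pairs are +inf; the diagonal is 0.  Binarized networks
    reduce to hop counts.
    """
    require_state(m, "thresholded", "binarized")
    w = m.weights
    if w.min() < 0:
        raise ConnectomeError("negative weights have no path-length interpretation")
    ii, jj = np.nonzero(w)
    lengths = csr_matrix((1.0 / w[ii, jj], (ii, jj)), shape=w.shape)
    return dijkstra(lengths, directed=False)


def distance_metrics(d: np.ndarray) -> dict[str, float]:
    """CPL, global efficiency, radius and diameter from a distance matrix.

    All four omit the diagonal and infinite entries.  A node's eccentricity
    is its largest finite distance; nodes with no finite partner do not
    contribute to radius/diameter.  With no finite off-diagonal entry at
    all, every value is NaN.
    """
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        return {
            "cpl": np.nan,
            "global_efficiency": np.nan,
            "radius": np.nan,
            "diameter": np.nan,
        }
    vals = d[finite]
    ecc = np.where(
        finite.any(axis=1),
        np.max(np.where(finite, d, -np.inf), axis=1),
        np.nan,
    )
    ecc = ecc[np.isfinite(ecc)]
    return {
        "cpl": float(vals.mean()),
        "global_efficiency": float((1.0 / vals).mean()),
        "radius": float(ecc.min()),
        "diameter": float(ecc.max()),
    }


def component_labels(m: ConnectivityMatrix) -> np.ndarray:
    adj = csr_matrix((m.weights != 0).astype(np.int8))
    _, labels = connected_components(adj, directed=False)
    return labels


def largest_cluster_size(m: ConnectivityMatrix) -> int:
    """Node count of the largest connected component (isolates count as 1)."""
    if m.n == 0:
        return 0
    labels = component_labels(m)
    return int(np.bincount(labels).max())


# ---------------------------------------------------------------------------
# nodal battery


def to_networkx(m: ConnectivityMatrix) -> nx.Graph:
    """Undirected graph with ``weight`` and ``length`` (=1/weight) edge attrs."""
    g = nx.Graph()
    g.add_nodes_from(range(m.n))
    ii, jj = np.nonzero(np.triu(m.weights, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        w = m.weights[i, j]
        g.add_edge(i, j, weight=w, length=1.0 / w)
    return g


def nodal_metrics(
    m: ConnectivityMatrix,
    metrics: Iterable[str] = NODAL_METRICS,
    seed: int = 0,
    restarts: int = 100,
) -> pd.DataFrame:
    """Per-node quantifier table (one row per region).

    ``participation`` triggers a Louvain community search (see
    :func:`community_metrics`); all other columns are deterministic.
    """
    require_state(m, "thresholded", "binarized")
    metrics = list(metrics)
    unknown = set(metrics) - set(NODAL_METRICS)
    if unknown:
        raise ConnectomeError(f"unknown nodal metrics: {sorted(unknown)}")
    w = m.weights
    out: dict[str, np.ndarray] = {}
    if "degree" in metrics:
        out["degree"] = (w != 0).sum(axis=1).astype(float)
    if "strength" in metrics:
        out["strength"] = w.sum(axis=1)
    g = None
    if {"betweenness", "clustering"} & set(metrics):
        g = to_networkx(m)
    if "betweenness" in metrics:
        bc = nx.betweenness_centrality(g, normalized=False, weight="length")
        out["betweenness"] = np.array([bc[i] for i in range(m.n)])
    if "eigenvector" in metrics:
        out["eigenvector"] = eigenvector_centrality(w)
    if "clustering" in metrics:
        cc = nx.clustering(g, weight="weight")
        out["clustering"] = np.array([cc[i] for i in range(m.n)])
    if "local_efficiency" in metrics:
        out["local_efficiency"] = local_efficiency(m)
    if "participation" in metrics:
        _, _, part = community_metrics(m, seed=seed, restarts=restarts)
        out["participation"] = part
    df = pd.DataFrame(out, index=pd.Index(list(m.labels), name="region"))
    return df[metrics]


def eigenvector_centrality(w: np.ndarray) -> np.ndarray:
    """Absolute leading eigenvector of the weight matrix, unit Euclidean norm.

    Disconnected graphs use the full matrix, so mass concentrates on the
    dominant component.  An edgeless matrix returns all zeros.
    """
    if not np.any(w):
        return np.zeros(w.shape[0])
    vals, vecs = np.linalg.eigh(w)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / np.linalg.norm(v)


def local_efficiency(m: ConnectivityMatrix) -> np.ndarray:
    """Efficiency of each node's neighborhood subgraph.

    For node i with degree >= 2, take the subgraph induced by its
    neighbors (original weights), and average 1/d over ordered neighbor
    pairs, scoring unreachable pairs as 0 so the value is always defined
    and bounded.  Degree < 2 gives 0.
    """
    w = m.weights
    n = m.n
    eff = np.zeros(n)
    neighbor_lists = [np.nonzero(w[i])[0] for i in range(n)]
    for i in range(n):
        nbrs = neighbor_lists[i]
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        ii, jj = np.nonzero(sub)
        if len(ii) == 0:
            continue
        lengths = csr_matrix((1.0 / sub[ii, jj], (ii, jj)), shape=sub.shape)
        d = dijkstra(lengths, directed=False)
        off = ~np.eye(k, dtype=bool)
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
        eff[i] = inv[off].mean()
    return eff


# ---------------------------------------------------------------------------
# communities


def community_metrics(
    m: ConnectivityMatrix, seed: int = 0, restarts: int = 100
) -> tuple[float, np.ndarray, np.ndarray]:
    """Best-of-``restarts`` Louvain partition, its modularity Q, and the
    participation coefficient of every node under that partition.

    Returns ``(Q, partition, participation)`` where ``partition[i]`` is the
    community id of node i.  Each restart shuffles the Louvain node order
    with a distinct seed derived from ``seed``; the partition with the
    largest weighted modularity (resolution 1) wins.  An edgeless network
    gets ``Q = NaN``, singleton communities and zero participation.
    """
    require_state(m, "thresholded", "binarized")
    g = to_networkx(m)
    if g.number_of_edges() == 0:
        return np.nan, np.arange(m.n), np.zeros(m.n)
    rng = np.random.default_rng(seed)
    best_q, best_part = -np.inf, None
    for _ in range(max(1, restarts)):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=1.0, seed=sub_seed
        )
        q = nx.community.modularity(g, comms, weight="weight", resolution=1.0)
        if q > best_q:
            best_q, best_part = q, comms
    partition = np.empty(m.n, dtype=int)
    for cid, comm in enumerate(best_part):
        for node in comm:
            partition[node] = cid
    return float(best_q), partition, participation_coefficient(m.weights, partition)


def participation_coefficient(w: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """p_i = 1 - sum_c (s_ic / s_i)^2 over communities c; isolates get 0."""
    n = w.shape[0]
    strength = w.sum(axis=1)
    p = np.zeros(n)
    n_comm = partition.max() + 1 if n else 0
    comm_strength = np.zeros((n, n_comm))
    for c in range(n_comm):
        comm_strength[:, c] = w[:, partition == c].sum(axis=1)
    connected = strength > 0
    frac = comm_strength[connected] / strength[connected, None]
    p[connected] = 1.0 - (frac**2).sum(axis=1)
    return p


# ---------------------------------------------------------------------------
# whole-network structure


def network_metrics(m: ConnectivityMatrix) -> dict[str, float]:
    """Weighted transitivity and assortativity.

    Transitivity uses geometric-mean triangle intensities over weights
    rescaled by the network maximum, divided by the number of connected
    triples; on binary networks this is the usual closed-triple ratio.
    Assortativity is the Pearson correlation of endpoint strengths across
    edges (strength equals degree on binary networks).  Networks with no
    length-2 paths, or with constant endpoint values, return NaN.
    """
    require_state(m, "thresholded", "binarized")
    w = m.weights
    peak = w.max()
    transitivity = np.nan
    if peak > 0:
        a = np.cbrt(w / peak)
        triangles = np.trace(a @ a @ a)  # counts each closed ordered triple
        k = (w != 0).sum(axis=1)
        triples = float((k * (k - 1)).sum())
        if triples > 0:
            transitivity = float(triangles / triples)
    return {
        "transitivity": transitivity,
        "assortativity": _strength_assortativity(w),
    }


def _strength_assortativity(w: np.ndarray) -> float:
    strength = w.sum(axis=1)
    ii, jj = np.nonzero(np.triu(w, k=1))
    if len(ii) < 2:
        return np.nan
    # both orientations of every edge, as in the standard degree-mixing sum
    x = np.concatenate([strength[ii], strength[jj]])
    y = np.concatenate([strength[jj], strength[ii]])
    if np.ptp(x) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def small_worldness(
    m: ConnectivityMatrix, n_null: int = 20, seed: int = 0
) -> float:
    """Small-world coefficient sigma = (C/C_rand) / (L/L_rand).

    C is the mean clustering coefficient and L the finite-pair CPL of the
    *binary* skeleton; C_rand and L_rand are their means over ``n_null``
    degree-preserving rewired null networks (10 successful double-edge
    swaps per edge, seeded).  Returns NaN when the null ensemble is
    degenerate (rewiring impossible or a zero ratio).
    """
    require_state(m, "thresholded", "binarized")
    skeleton = m.with_weights((m.weights != 0).astype(float), state="binarized")
    if largest_cluster_size(skeleton) < 10:
        raise ConnectomeError("small-worldness needs a largest component of >= 10 nodes")
    g = to_networkx(skeleton)
    n_edges = g.number_of_edges()
    c_obs = np.mean(list(nx.clustering(g).values()))
    l_obs = distance_metrics(shortest_path_lengths(skeleton))["cpl"]
    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    for _ in range(n_null):
        h = g.copy()
        try:
            nx.double_edge_swap(
                h,
                nswap=10 * n_edges,
                max_tries=1000 * n_edges,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        except nx.NetworkXError:
            return np.nan
        c_null.append(np.mean(list(nx.clustering(h).values())))
        null_m = _graph_to_matrix(h, m.n)
        l_null.append(distance_metrics(shortest_path_lengths(null_m))["cpl"])
    c_rand, l_rand = np.mean(c_null), np.mean(l_null)
    if c_rand <= 0 or l_rand <= 0 or not np.isfinite(l_obs):
        return np.nan
    return float((c_obs / c_rand) / (l_obs / l_rand))


def _graph_to_matrix(g: nx.Graph, n: int) -> ConnectivityMatrix:
    w = np.zeros((n, n))
    for i, j in g.edges():
        w[i, j] = w[j, i] = 1.0
    return ConnectivityMatrix(
        weights=w, labels=tuple(f"R{i}" for i in range(n)), state="binarized"
    )


def degree_distribution_summary(m: ConnectivityMatrix) -> dict[str, object]:
    """Degree histogram plus the fraction of nodes beyond twice the mean degree."""
    degrees = (m.weights != 0).sum(axis=1)
    hist = np.bincount(degrees.astype(int), minlength=1)
    mean = degrees.mean() if m.n else 0.0
    tail = float((degrees > 2 * mean).mean()) if m.n and mean > 0 else 0.0
    return {"histogram": hist, "mean_degree": float(mean), "tail_fraction": tail}


# ---------------------------------------------------------------------------
# the Table-1 style global record


@dataclass
class GlobalQuantifierSet:
    """One row of global quantifiers for a single network snapshot."""

    cpl: float = np.nan
    global_efficiency: float = np.nan
    radius: float = np.nan
    diameter: float = np.nan
    largest_cluster: float = np.nan
    density: float = np.nan
    n_edges: float = np.nan
    avg_degree: float = np.nan
    modularity: float = np.nan
    transitivity: float = np.nan
    assortativity: float = np.nan
    small_worldness: float = np.nan
    avg_cc: float = np.nan
    avg_st: float = np.nan
    avg_bc: float = np.nan
    avg_ec: float = np.nan
    avg_le: float = np.nan
    avg_pc: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(cls))


GLOBAL_METRICS = GlobalQuantifierSet.field_names()

_DISTANCE_FIELDS = {"cpl", "global_efficiency", "radius", "diameter"}
_NODAL_AVG = {
    "avg_cc": "clustering",
    "avg_st": "strength",
    "avg_bc": "betweenness",
    "avg_ec": "eigenvector",
    "avg_le": "local_efficiency",
}


def compute_global_quantifiers(
    m: ConnectivityMatrix,
    metrics: Sequence[str] | None = None,
    seed: int = 0,
    restarts: int = 100,
    include_sigma: bool = False,
    n_null: int = 20,
) -> GlobalQuantifierSet:
    """Assemble the full global quantifier record for one network.

    ``metrics=None`` computes everything except small-worldness, which is
    expensive and opt-in via ``include_sigma`` (or by listing
    ``"small_worldness"`` explicitly).  Unrequested fields are NaN.
    """
    if metrics is None:
        metrics = [f for f in GLOBAL_METRICS if f != "small_worldness"]
        if include_sigma:
            metrics = list(metrics) + ["small_worldness"]
    wanted = set(metrics)
    unknown = wanted - set(GLOBAL_METRICS)
    if unknown:
        raise ConnectomeError(f"unknown global metrics: {sorted(unknown)}")
    out = GlobalQuantifierSet()

    if wanted & _DISTANCE_FIELDS:
        dm = distance_metrics(shortest_path_lengths(m))
        for key in wanted & _DISTANCE_FIELDS:
            setattr(out, key, dm[key])
    if "largest_cluster" in wanted:
        out.largest_cluster = float(largest_cluster_size(m))
    if "density" in wanted:
        out.density = m.density
    if "n_edges" in wanted:
        out.n_edges = float(m.n_edges)
    if "avg_degree" in wanted:
        out.avg_degree = 2.0 * m.n_edges / m.n if m.n else np.nan
    if wanted & {"transitivity", "assortativity"}:
        nm = network_metrics(m)
        if "transitivity" in wanted:
            out.transitivity = nm["transitivity"]
        if "assortativity" in wanted:
            out.assortativity = nm["assortativity"]
    needs_partition = wanted & {"modularity", "avg_pc"}
    if needs_partition:
        q, _, part = community_metrics(m, seed=seed, restarts=restarts)
        if "modularity" in wanted:
            out.modularity = q
        if "avg_pc" in wanted:
            out.avg_pc = float(part.mean())
    nodal_wanted = [f for f in wanted if f in _NODAL_AVG]
    if nodal_wanted:
        table = nodal_metrics(m, metrics=[_NODAL_AVG[f] for f in nodal_wanted])
        for f in nodal_wanted:
            setattr(out, f, float(table[_NODAL_AVG[f]].mean()))
    if "small_worldness" in wanted:
        out.small_worldness = small_worldness(m, n_null=n_null, seed=seed)
    return out
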