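"""Reading and writing connectivity matrices, atlases and BrainNet Viewer files.

Two adjacency dialects are supported: labelled CSV (row and column headers
carry region labels, the primary on-disk format) and headerless
whitespace-separated matrices, which doubles as the BrainNet Viewer ``.edge``
format.  Atlases are tab-separated tables with columns
``label, hemisphere, x, y, z``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, ConnectomeError, RegionAtlas, require_state

logger = logging.getLogger(__name__)

ASYMMETRY_WARN_TOL = 1e-6


def read_matrix(
    path: str | Path,
    dialect: Literal["labelled-csv", "plain-whitespace"] = "labelled-csv",
    subject_id: str = "",
    group: str = "control",
) -> ConnectivityMatrix:
    """Read an adjacency matrix file into a raw-state :class:`ConnectivityMatrix`.

    Asymmetric inputs are symmetrized by averaging ``(W + W.T) / 2``;
    asymmetry beyond 1e-6 is logged but not rejected, since Pearson matrices
    should be symmetric up to float noise.  The diagonal is forced to zero.
    """
    path = Path(path)
    if dialect == "labelled-csv":
        df = pd.read_csv(path, index_col=0)
        if df.shape[0] != df.shape[1]:
            raise ConnectomeError(
                f"{path}: non-square block {df.shape[0]}x{df.shape[1]}"
            )
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ConnectomeError(f"{path}: row and column headers differ")
        labels = tuple(str(c) for c in df.columns)
        w = _numeric_block(df, path)
    elif dialect == "plain-whitespace":
        try:
            w = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise ConnectomeError(f"{path}: non-numeric cell ({exc})") from exc
        if w.shape[0] != w.shape[1]:
            raise ConnectomeError(
                f"{path}: non-square block {w.shape[0]}x{w.shape[1]}"
            )
        labels = tuple(f"R{i}" for i in range(w.shape[0]))
    else:
        raise ConnectomeError(f"unknown dialect {dialect!r}")

    asym = np.abs(w - w.T).max() if w.size else 0.0
    if asym > ASYMMETRY_WARN_TOL:
        logger.warning("%s: asymmetry up to %.3g symmetrized by averaging", path, asym)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        weights=w, labels=labels, subject_id=subject_id or path.stem, group=group
    )


def _numeric_block(df: pd.DataFrame, path: Path) -> np.ndarray:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    if coerced.isna().any().any():
        bad = np.argwhere(coerced.isna().to_numpy())[0]
        raise ConnectomeError(
            f"{path}: non-numeric cell at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    return coerced.to_numpy(dtype=float)


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> None:
    """Write a matrix as labelled CSV (round-trips through :func:`read_matrix`)."""
    df = pd.DataFrame(m.weights, index=list(m.labels), columns=list(m.labels))
    df.to_csv(path, float_format="%.10g")


def read_atlas(path: str | Path) -> RegionAtlas:
    """Read a tab-separated atlas table (label, hemisphere, x, y, z)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"label", "hemisphere", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ConnectomeError(f"{path}: atlas missing columns {sorted(missing)}")
    return RegionAtlas(
        labels=tuple(df["label"].astype(str)),
        hemispheres=tuple(df["hemisphere"].astype(str)),
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


def write_brainnet_files(
    m: ConnectivityMatrix,
    atlas: RegionAtlas,
    prefix: str | Path,
    node_sizes: Sequence[float] | None = None,
    node_colors: Sequence[int] | None = None,
) -> tuple[Path, Path]:
    """Emit BrainNet Viewer ``<prefix>.node`` and ``<prefix>.edge`` files.

    The ``.node`` file has six whitespace-separated columns per region:
    x, y, z, color, size, label.  ``node_colors`` defaults to 1 for every
    region (pass a module partition id per node to color by community);
    ``node_sizes`` defaults to degree and is rescaled to [1, 10].
    The ``.edge`` file is the full n-by-n weight matrix, one row per line,
    at 6-decimal precision.
    """
    if m.n != atlas.n_regions:
        raise ConnectomeError(
            f"matrix has {m.n} nodes but atlas has {atlas.n_regions} regions"
        )
    prefix = Path(prefix)
    if node_sizes is None:
        node_sizes = (m.weights != 0).sum(axis=1).astype(float)
    sizes = _rescale_sizes(np.asarray(node_sizes, dtype=float))
    colors = (
        np.ones(m.n, dtype=int)
        if node_colors is None
        else np.asarray(node_colors, dtype=int)
    )
    if len(sizes) != m.n or len(colors) != m.n:
        raise ConnectomeError("node size/color vectors must match node count")

    node_path = prefix.with_suffix(".node")
    edge_path = prefix.with_suffix(".edge")
    with open(node_path, "w") as fh:
        for i in range(m.n):
            x, y, z = atlas.coords[i]
            label = str(atlas.labels[i]).replace(" ", "_")
            fh.write(
                f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{colors[i]:d}\t{sizes[i]:.3f}\t{label}\n"
            )
    np.savetxt(edge_path, m.weights, fmt="%.6f", delimiter=" ")
    return node_path, edge_path


def _rescale_sizes(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, 5.5)
    return 1.0 + 9.0 * (v - lo) / (hi - lo)


def connection_length_classes(
    m: ConnectivityMatrix,
    atlas: RegionAtlas,
    cutoff_mm: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify each edge as long- or short-range by Euclidean node distance.

    An edge (i, j) is ``long`` iff the inter-node distance exceeds
    ``cutoff_mm``.  The cutoff defaults to the median pairwise atlas
    distance, an arbitrary but reproducible midpoint.  Returns a per-edge
    table and class counts; the two classes always partition the edge set.
    """
    require_state(m, "thresholded", "binarized")
    if m.n != atlas.n_regions:
        raise ConnectomeError("matrix/atlas size mismatch")
    dist = atlas.pairwise_distances()
    if cutoff_mm is None:
        iu = np.triu_indices(m.n, k=1)
        cutoff_mm = float(np.median(dist[iu]))
    if cutoff_mm <= 0:
        raise ConnectomeError("cutoff_mm must be positive")
    ii, jj = np.nonzero(np.triu(m.weights, k=1))
    d = dist[ii, jj]
    labels = np.where(d > cutoff_mm, "long", "short")
    table = pd.DataFrame(
        {
            "i": ii,
            "j": jj,
            "weight": m.weights[ii, jj],
            "distance_mm": d,
            "length_class": labels,
        }
    )
    counts = {
        "long": int((labels == "long").sum()),
        "short": int((labels == "short").sum()),
    }
    return table, counts
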