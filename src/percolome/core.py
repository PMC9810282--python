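"""Core domain objects: region atlases and weighted connectivity matrices.

A functional connectome is represented as a symmetric region-by-region matrix
of pairwise Pearson correlations between regional BOLD time series.  The
matrix moves through a small processing state machine::

    raw -> normalized -> thresholded -> binarized

``raw`` matrices carry signed correlations in [-1, 1]; normalization clips
negatives and rescales to [0, 1]; proportional thresholding keeps the
top-density fraction of edges; binarization maps surviving weights to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

State = Literal["raw", "normalized", "thresholded", "binarized"]
Group = Literal["control", "disease"]

#: allowed processing states, in pipeline order
STATES: tuple[str, ...] = ("raw", "normalized", "thresholded", "binarized")

SYMMETRY_TOL = 1e-9


class ConnectomeError(ValueError):
    """Base error for malformed connectome inputs."""


@dataclass(frozen=True)
class RegionAtlas:
    """Brain-region parcellation table: labels, hemispheres and coordinates.

    Parameters
    ----------
    labels
        Unique region names, index-aligned with matrix rows.
    hemispheres
        One of ``"L"``, ``"R"``, ``"midline"`` per region.
    coords
        ``(n, 3)`` array of x/y/z positions in mm atlas space.
    """

    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ConnectomeError("atlas labels must be unique")
        if len(self.hemispheres) != n or coords.shape != (n, 3):
            raise ConnectomeError("atlas fields must have matching lengths")
        bad = set(self.hemispheres) - {"L", "R", "midline"}
        if bad:
            raise ConnectomeError(f"unknown hemisphere codes: {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def bilateral_pairs(self) -> list[tuple[int, int]]:
        """Match L/R region pairs by their label stem.

        The stem is the label with a trailing or leading hemisphere marker
        (``_L``/``_R`` suffix or ``Left ``/``Right `` style prefix) removed.
        Regions without a contralateral partner are omitted.
        """
        stems: dict[str, dict[str, int]] = {}
        for i, (lab, hemi) in enumerate(zip(self.labels, self.hemispheres)):
            if hemi == "midline":
                continue
            stem = _label_stem(lab, hemi)
            stems.setdefault(stem, {})[hemi] = i
        pairs = []
        for stem, sides in sorted(stems.items()):
            if "L" in sides and "R" in sides:
                pairs.append((sides["L"], sides["R"]))
        return pairs

    def unpaired_regions(self) -> list[int]:
        """Indices of lateralized regions lacking a contralateral partner."""
        paired = {i for pair in self.bilateral_pairs() for i in pair}
        return [
            i
            for i, h in enumerate(self.hemispheres)
            if h in ("L", "R") and i not in paired
        ]

    def pairwise_distances(self) -> np.ndarray:
        """Euclidean inter-region distance matrix in mm."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "hemisphere": self.hemispheres,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
            }
        )


def _label_stem(label: str, hemi: str) -> str:
    for suffix in (f"_{hemi}", f" {hemi}", f".{hemi}"):
        if label.endswith(suffix):
            return label[: -len(suffix)]
    for prefix in (f"{hemi}_", f"{hemi} "):
        if label.startswith(prefix):
            return label[len(prefix):]
    return label


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted region-by-region network with processing metadata.

    ``weights`` is an ``(n, n)`` float array, symmetric with a zero diagonal.
    Entry bounds depend on ``state`` (see module docstring).
    """

    weights: np.ndarray
    labels: tuple[str, ...]
    subject_id: str = ""
    group: str = "control"
    state: str = "raw"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.labels = tuple(self.labels)
        self.validate()

    def validate(self) -> None:
        w = self.weights
        n = len(self.labels)
        if w.shape != (n, n):
            raise ConnectomeError(
                f"weights shape {w.shape} does not match {n} labels"
            )
        if self.state not in STATES:
            raise ConnectomeError(f"unknown state {self.state!r}")
        if not np.allclose(w, w.T, atol=SYMMETRY_TOL, rtol=0.0):
            raise ConnectomeError("weights must be symmetric to within 1e-9")
        if np.any(np.diag(w) != 0.0):
            raise ConnectomeError("diagonal must be exactly zero")
        if self.state == "raw":
            lo, hi = -1.0, 1.0
        elif self.state == "binarized":
            if not np.isin(w, (0.0, 1.0)).all():
                raise ConnectomeError("binarized entries must be 0 or 1")
            return
        else:
            lo, hi = 0.0, 1.0
        if w.min() < lo - 1e-12 or w.max() > hi + 1e-12:
            raise ConnectomeError(
                f"state={self.state} entries must lie in [{lo}, {hi}]"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        """Number of nonzero upper-triangle entries."""
        iu = np.triu_indices(self.n, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    @property
    def density(self) -> float:
        """Graph density E / [n(n-1)/2]."""
        n = self.n
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1) / 2)

    def with_weights(self, weights: np.ndarray, state: str | None = None) -> "ConnectivityMatrix":
        """Copy carrying new weights (and optionally a new state)."""
        return ConnectivityMatrix(
            weights=np.array(weights, dtype=float),
            labels=self.labels,
            subject_id=self.subject_id,
            group=self.group,
            state=state or self.state,
        )

    def copy(self) -> "ConnectivityMatrix":
        return self.with_weights(self.weights.copy())


def require_state(m: ConnectivityMatrix, *states: str) -> None:
    if m.state not in states:
        raise ConnectomeError(
            f"operation requires state in {states}, got {m.state!r}"
        )


def check_aligned(ms: Sequence[ConnectivityMatrix]) -> None:
    """Raise unless all matrices share identical region labels."""
    if not ms:
        raise ConnectomeError("need at least one matrix")
    ref = ms[0].labels
    for m in ms[1:]:
        if m.labels != ref:
            raise ConnectomeError("matrices have mismatched region labels")
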