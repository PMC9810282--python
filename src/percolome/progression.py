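"""Progression modelling: attacked control networks vs the diseased baseline.

The disease-progression question is whether a targeted attack on the
healthy group-average network drives its quantifiers toward the values of
the *unattacked* diseased network.  The difference curve is

    delta_t = q_disease(baseline) - q_control(after t attacks)

and the crossing step is the (possibly fractional) attack count at which
the curve first changes sign relative to its starting side — i.e. the
attacked control network first reaches the diseased level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attack import AttackTrajectory, remove_node
from .core import ConnectivityMatrix, ConnectomeError
from .quantifiers import GlobalQuantifierSet, component_labels


@dataclass
class ProgressionResult:
    quantifier_name: str
    scheme: str
    diff_curve: np.ndarray
    crossing_step: float


def baseline_difference_curve(
    traj: AttackTrajectory, baseline: GlobalQuantifierSet, quantifier: str
) -> np.ndarray:
    """delta_t = baseline value minus the trajectory value after t removals."""
    base = getattr(baseline, quantifier, None)
    if base is None or not np.isfinite(base):
        raise ConnectomeError(f"baseline lacks a finite {quantifier!r} value")
    return base - traj.curve(quantifier)


def attacks_to_reach_baseline(diff_curve: np.ndarray) -> float:
    """First (fractional) step where the difference curve reaches zero.

    An exact zero at step t reports t; a strict sign change between t-1 and
    t is linearly interpolated; a curve that never leaves its starting side
    reports +inf.  A curve starting at exactly zero reports 0.  NaN steps
    (quantifier undefined on a fragmented snapshot) are skipped: crossings
    are only declared between finite values.
    """
    d = np.asarray(diff_curve, dtype=float)
    if d.size == 0:
        raise ConnectomeError("empty difference curve")
    finite = np.where(np.isfinite(d))[0]
    if finite.size == 0:
        return np.inf
    start = finite[0]
    s0 = np.sign(d[start])
    if s0 == 0:
        return float(start)
    prev = start
    for t in finite[1:]:
        if np.sign(d[t]) == 0:
            return float(t)
        if np.sign(d[t]) != s0:
            # interpolate between the flanking finite steps
            frac = d[prev] / (d[prev] - d[t])
            return float(prev + frac * (t - prev))
        prev = t
    return np.inf


def progression_result(
    traj: AttackTrajectory, baseline: GlobalQuantifierSet, quantifier: str
) -> ProgressionResult:
    curve = baseline_difference_curve(traj, baseline, quantifier)
    return ProgressionResult(
        quantifier_name=quantifier,
        scheme=f"{traj.scheme}:{traj.quantifier_name}",
        diff_curve=curve,
        crossing_step=attacks_to_reach_baseline(curve),
    )


def shared_early_attacks(
    order_a: list[int], order_b: list[int], k: int
) -> set[int]:
    """Nodes appearing in the first ``k`` removals of both attack orders."""
    if k < 0 or k > len(order_a) or k > len(order_b):
        raise ConnectomeError(f"k={k} out of range for the given orders")
    return set(order_a[:k]) & set(order_b[:k])


def disconnected_after(
    m: ConnectivityMatrix, removed: list[int]
) -> set[int]:
    """Surviving nodes severed from the largest component by the removals.

    Applies :func:`remove_node` for each listed node, then returns every
    *surviving* node outside the largest connected component — isolates and
    minor fragments — excluding the removed nodes themselves.  Ties for the
    largest component are broken by keeping the component containing the
    lowest node index.
    """
    current = m.copy()
    for node in removed:
        current = remove_node(current, node)
    labels = component_labels(current)
    survivors = np.setdiff1d(np.arange(m.n), np.asarray(removed, dtype=int))
    if survivors.size == 0:
        return set()
    # the reference giant is chosen among surviving nodes' components only
    sizes = np.bincount(labels)
    surv_sizes = sizes[labels[survivors]]
    best = surv_sizes.max()
    # lowest-index tie break: first survivor whose component has maximal size
    giant = labels[survivors[np.argmax(surv_sizes == best)]]
    return {int(i) for i in survivors if labels[i] != giant}
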