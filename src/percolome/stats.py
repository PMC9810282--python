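"""Nonparametric group comparison of network quantifiers.

Subject-level quantifiers are compared between groups with the two-sided
Wilcoxon rank-sum test (normal approximation with tie and continuity
corrections; exact enumeration available for small samples) and the effect
size r = |z| / sqrt(n1 + n2).  P-values are reported uncorrected across
quantifiers — the faithful convention for this analysis style, but with
~15 global and several hundred nodal tests the family-wise error rate is
substantial, so treat isolated nodal significances with caution.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ConnectomeError


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], exact: bool = False
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(z, p)``.

    ``z`` is signed: positive when sample ``a`` tends to rank above ``b``.
    The normal approximation applies the tie correction to the variance
    and a 0.5 continuity correction toward zero.  With ``exact=True`` and
    no ties, the p-value comes from exact permutation enumeration instead
    (the z statistic is still the corrected normal one).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConnectomeError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    # tie correction to the rank-sum variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    if exact:
        if len(counts) == n:  # no ties
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            return float(z), float(res.pvalue)
        raise ConnectomeError("exact enumeration requires tie-free samples")
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def effect_size_r(z: float, n_total: int) -> float:
    """r = |z| / sqrt(n_total), the rank-sum effect size."""
    if n_total < 2:
        raise ConnectomeError("effect size needs n_total >= 2")
    return abs(z) / np.sqrt(n_total)


def compare_quantifiers(
    group_a: pd.DataFrame, group_b: pd.DataFrame, exact: bool = False
) -> pd.DataFrame:
    """Metric-by-metric group comparison table.

    Each input frame has one row per subject and one column per metric
    (nodal tables may use flattened ``node|metric`` column names).  Output
    rows carry mean, SE (= SD/sqrt(n)) and SD per group, the signed z, the
    two-sided p and the effect size r, sorted by ascending p.  P-values are
    uncorrected (see module docstring).
    """
    if group_a.shape[0] < 2 or group_b.shape[0] < 2:
        raise ConnectomeError("need at least two subjects per group")
    if list(group_a.columns) != list(group_b.columns):
        raise ConnectomeError("metric columns are not aligned between groups")
    rows = []
    for col in group_a.columns:
        x = group_a[col].to_numpy(dtype=float)
        y = group_b[col].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if x.size < 2 or y.size < 2:
            continue
        z, p = rank_sum_test(x, y, exact=exact)
        rows.append(
            {
                "metric": col,
                "mean_a": x.mean(),
                "se_a": x.std(ddof=1) / np.sqrt(x.size),
                "sd_a": x.std(ddof=1),
                "mean_b": y.mean(),
                "se_b": y.std(ddof=1) / np.sqrt(y.size),
                "sd_b": y.std(ddof=1),
                "z": z,
                "p": p,
                "r": effect_size_r(z, x.size + y.size),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
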