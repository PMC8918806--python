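"""Group-level summaries: coefficient of variation, percent differences
between conditions, and condition clustering.

Clustering reproduces the common heat-map setting for condition profiles:
agglomerative, distance = 1 − Pearson correlation between condition rows,
average linkage, leaves ordered tightest-cluster-first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

__all__ = [
    "GroupSummary",
    "coefficient_of_variation",
    "percent_difference_table",
    "cluster_conditions",
    "leaf_order_tightest_first",
    "summarise_groups",
]


@dataclass
class GroupSummary:
    """Per-group mean/sd/CoV% for each parameter plus pairwise percent
    differences and, when ≥2 conditions are summarised, a linkage tree."""

    stats: pd.DataFrame  # index (group, parameter), columns mean/sd/cov_percent
    percent_diff: pd.DataFrame | None = None
    linkage_matrix: np.ndarray | None = None
    leaf_order: list[int] | None = None
    flags: list[str] = field(default_factory=list)


def coefficient_of_variation(values) -> float:
    """CoV% = 100·sd/mean with the sample (n−1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CoV needs at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CoV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def percent_difference_table(
    control: pd.DataFrame, treated: pd.DataFrame
) -> pd.Series:
    """Per-parameter percent difference of group means.

    100·(mean_treated − mean_control)/mean_control over the shared numeric
    columns; a zero control mean yields NaN (flag it downstream rather than
    dividing).
    """
    if control.empty or treated.empty:
        raise ValueError("both groups must be non-empty")
    cols = [
        c
        for c in control.columns
        if c in treated.columns and pd.api.types.is_numeric_dtype(control[c])
    ]
    if not cols:
        raise ValueError("no shared numeric parameters")
    mc = control[cols].mean()
    mt = treated[cols].mean()
    out = pd.Series(index=cols, dtype=float)
    for c in cols:
        out[c] = np.nan if mc[c] == 0 else 100.0 * (mt[c] - mc[c]) / mc[c]
    return out


def cluster_conditions(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Average-linkage agglomeration of condition profiles under correlation
    distance (1 − Pearson r between rows).

    Returns the SciPy linkage matrix and the leaf order with the tightest
    (lowest-merge-distance) subtree placed first at every internal node;
    ties keep input order.  Constant rows have undefined correlation and
    raise.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 conditions and >= 2 parameters")
    if np.any(X.std(axis=1) == 0):
        raise ValueError("constant condition profile: correlation distance undefined")
    d = pdist(X, metric="correlation")
    Z = linkage(d, method="average")
    return Z, leaf_order_tightest_first(Z)


def leaf_order_tightest_first(Z: np.ndarray) -> list[int]:
    """Leaf ordering that recursively visits the child merged at the smaller
    height first (tightest cluster first)."""
    n = Z.shape[0] + 1
    heights = {i: 0.0 for i in range(n)}
    children = {}
    for k, (a, b, h, _) in enumerate(Z):
        node = n + k
        heights[node] = float(h)
        children[node] = (int(a), int(b))

    def min_leaf(node: int) -> int:
        if node < n:
            return node
        a, b = children[node]
        return min(min_leaf(a), min_leaf(b))

    def visit(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        # smaller subtree height first; ties (within float noise of the
        # distance computation) broken by condition input order
        if heights[b] < heights[a] - 1e-12:
            a, b = b, a
        elif abs(heights[b] - heights[a]) <= 1e-12 and min_leaf(b) < min_leaf(a):
            a, b = b, a
        return visit(a) + visit(b)

    return visit(2 * n - 2)


def summarise_groups(
    records: pd.DataFrame,
    group_col: str = "group",
    control_group: str | None = None,
) -> GroupSummary:
    """Mean, sd and CoV% per group and parameter, plus percent differences
    of every group against ``control_group`` and a condition clustering when
    at least two non-control groups share the parameters."""
    numeric = [
        c for c in records.columns if c != group_col and pd.api.types.is_numeric_dtype(records[c])
    ]
    rows = []
    flags: list[str] = []
    for g, df in records.groupby(group_col):
        for c in numeric:
            v = df[c].dropna().to_numpy(dtype=float)
            mean = v.mean() if v.size else np.nan
            sd = v.std(ddof=1) if v.size > 1 else np.nan
            cov = 100.0 * sd / mean if v.size > 1 and mean != 0 else np.nan
            if v.size > 1 and mean == 0:
                flags.append(f"zero-mean:{g}:{c}")
            rows.append({"group": g, "parameter": c, "mean": mean, "sd": sd, "cov_percent": cov})
    stats = pd.DataFrame(rows).set_index(["group", "parameter"])

    pdiff = None
    if control_group is not None:
        ctrl = records[records[group_col] == control_group][numeric]
        entries = {}
        for g, df in records.groupby(group_col):
            if g == control_group:
                continue
            entries[g] = percent_difference_table(ctrl, df[numeric])
        if entries:
            pdiff = pd.DataFrame(entries).T

    Z = order = None
    if pdiff is not None and len(pdiff) >= 2 and pdiff.shape[1] >= 2 and not pdiff.isna().any().any():
        try:
            Z, order = cluster_conditions(pdiff)
        except ValueError as exc:
            flags.append(f"clustering-skipped:{exc}")
    return GroupSummary(stats, pdiff, Z, order, flags)
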