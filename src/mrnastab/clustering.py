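"""Ward hierarchical clustering of per-gene half-life profiles.

Genes with a reliable half-life in every studied growth condition form
profiles (one half-life per condition, in minutes); agglomerative clustering
with Ward's minimum-variance linkage on Euclidean distances groups genes
whose stability responds similarly to growth rate.  The flat cut is by a
requested cluster count (chosen graphically from the dendrogram in
practice), and cluster summaries report per-condition means with two-sided
t-based confidence intervals.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy import stats

__all__ = ["ward_cluster", "cluster_summary", "linkage_to_newick"]


def ward_cluster(
    profiles: pd.DataFrame, n_clusters: int, log: bool = False
) -> tuple[pd.Series, np.ndarray]:
    """Ward clustering of a gene x condition half-life table.

    Distances are Euclidean on raw half-lives in minutes (all coordinates
    share units); pass ``log=True`` to cluster ln half-lives instead.
    Returns flat labels (1..n_clusters, deterministic given row order) and
    the full linkage matrix.  Profiles may contain no missing values.
    """
    if profiles.isna().any().any():
        raise ValueError("profiles must be complete; filter genes upstream")
    n = profiles.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    x = profiles.to_numpy(dtype=float)
    if log:
        if (x <= 0).any():
            raise ValueError("log scaling requires positive half-lives")
        x = np.log(x)
    linkage = hierarchy.linkage(x, method="ward")
    labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=profiles.index, name="cluster"), linkage


def cluster_summary(
    profiles: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster, per-condition mean half-life with (1 - alpha) t-CI.

    The interval half-width is t_{1-alpha/2, n-1} * sd / sqrt(n); for
    singleton clusters the CI is undefined (NaN half-width).  Clusters of
    identical members get zero-width intervals.
    """
    if not profiles.index.equals(labels.index):
        labels = labels.loc[profiles.index]
    rows = []
    for cluster, sub in profiles.groupby(labels):
        n = sub.shape[0]
        for cond in profiles.columns:
            x = sub[cond].to_numpy(dtype=float)
            mean = float(x.mean())
            if n > 1:
                half = float(stats.t.ppf(1 - alpha / 2, n - 1)
                             * x.std(ddof=1) / math.sqrt(n))
            else:
                half = math.nan
            rows.append((cluster, cond, n, mean, mean - half, mean + half))
    return pd.DataFrame(
        rows,
        columns=["cluster", "condition", "n", "mean", "ci_low", "ci_high"],
    )


def linkage_to_newick(linkage: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a linkage matrix as a Newick tree (merge heights as branch
    lengths), for plotting in standard tree viewers."""
    tree = hierarchy.to_tree(linkage)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"
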