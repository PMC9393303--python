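"""Cross-score analytics: Spearman correlation of pathway and immune scores
with unsupervised clustering, and the three-way hub-gene intersection.

Hub genes are defined as the intersection of three gene sets — in the
original analysis, differential genes from the single-cell trajectory,
differential genes from the bulk tumor-vs-normal comparison, and the
ferroptosis pathway gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations with an average-linkage dendrogram."""

    rho: pd.DataFrame
    pval: pd.DataFrame
    linkage: np.ndarray | None     # scipy linkage over 1 - rho distances
    clustered_labels: list[str]    # columns that entered the clustering
    excluded: list[str]            # constant columns, correlations undefined

    def newick(self) -> str:
        """Dendrogram as a Newick string with branch lengths."""
        if self.linkage is None:
            raise ValueError("no dendrogram: fewer than 2 usable columns")
        tree = hierarchy.to_tree(self.linkage)
        labels = self.clustered_labels

        def rec(node, parent_dist):
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def spearman_matrix(score_table: pd.DataFrame, bh: bool = False) -> CorrelationMatrix:
    """Average-rank Spearman correlation matrix over score columns.

    p-values use the two-sided t approximation and are reported raw by
    default (``bh=True`` applies Benjamini-Hochberg across the pairs).
    Constant columns have undefined correlations: they are set to NaN,
    flagged, and excluded from the clustering of 1 - rho distances.
    """
    if score_table.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    if score_table.shape[1] < 2:
        raise ValueError("need at least 2 score columns")
    cols = score_table.columns.tolist()
    arr = score_table.to_numpy(dtype=float)
    constant = [c for c, col in zip(cols, arr.T) if np.all(col == col[0])]
    if constant:
        logger.warning("constant score column(s) excluded from clustering: %s", constant)

    n = len(cols)
    rho = np.eye(n)
    pval = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if cols[i] in constant or cols[j] in constant:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(arr[:, i], arr[:, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    if bh:
        from .de import bh_adjust

        iu = np.triu_indices(n, k=1)
        flat = pval[iu]
        ok = np.isfinite(flat)
        adj = flat.copy()
        adj[ok] = bh_adjust(flat[ok])
        pval[iu] = adj
        pval.T[iu] = adj

    usable = [c for c in cols if c not in constant]
    linkage = None
    if len(usable) >= 2:
        idx = [cols.index(c) for c in usable]
        sub = rho[np.ix_(idx, idx)]
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        pval=pd.DataFrame(pval, index=cols, columns=cols),
        linkage=linkage, clustered_labels=usable, excluded=constant,
    )


def hub_gene_intersection(
    set_a: Iterable[str], set_b: Iterable[str], set_c: Iterable[str],
) -> tuple[list[str], dict[str, int]]:
    """Exact three-way intersection, sorted lexicographically, plus the
    per-region overlap counts needed to draw a Venn diagram."""
    a, b, c = frozenset(set_a), frozenset(set_b), frozenset(set_c)
    for name, s in (("a", a), ("b", b), ("c", c)):
        if not s:
            logger.warning("input set %s is empty: intersection is trivially empty", name)
    hub = sorted(a & b & c)
    counts = {
        "a": len(a), "b": len(b), "c": len(c),
        "ab": len(a & b), "ac": len(a & c), "bc": len(b & c),
        "abc": len(hub),
    }
    return hub, counts
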