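"""Single-cell quality control and cluster-marker filters.

Cells are filtered first, on three rules evaluated on the raw count matrix:
detected genes per cell within [200, 20000], and mitochondrial count
fraction strictly below 0.05 (mitochondrial genes recognized by an ID
pattern, "MT-" prefix by default). Genes detected in fewer than 3 of the
remaining cells are then removed. All thresholds are configurable.

Cluster markers are genes that, within a cluster versus all other cells,
are detected in at least ``min_pct`` of the cluster, change by at least
``min_log_fc`` in log2 of pseudocounted means, and pass a BH-adjusted
Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_MITO_PATTERN = r"^MT-"


@dataclass(frozen=True)
class QCThresholds:
    min_cells_per_gene: int = 3
    min_features_per_cell: int = 200
    max_mito_fraction: float = 0.05
    genes_per_cell_range: tuple[int, int] = (200, 20000)

    def __post_init__(self) -> None:
        lo, hi = self.genes_per_cell_range
        if lo > hi:
            raise ValueError("genes_per_cell_range low bound exceeds high bound")
        if not (0 <= self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class MarkerCriteria:
    min_pct: float = 0.25
    min_log_fc: float = 0.25
    adjusted_p_max: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.min_pct <= 1):
            raise ValueError("min_pct must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-rule removal counts from a QC pass.

    A cell can fail several rules, so per-rule counts can sum to more than
    the union of removed cells.
    """

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    failed_min_features: list[str] = field(default_factory=list)
    failed_max_features: list[str] = field(default_factory=list)
    failed_mito: list[str] = field(default_factory=list)
    removed_cells: list[str] = field(default_factory=list)
    removed_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            "n_failed_min_features": len(self.failed_min_features),
            "n_failed_max_features": len(self.failed_max_features),
            "n_failed_mito": len(self.failed_mito),
            "n_removed_cells": len(self.removed_cells),
            "n_removed_genes": len(self.removed_genes),
            "failed_min_features": self.failed_min_features,
            "failed_max_features": self.failed_max_features,
            "failed_mito": self.failed_mito,
            "removed_cells": self.removed_cells,
            "removed_genes": self.removed_genes,
        }


def apply_cell_qc(
    matrix: ExpressionMatrix,
    thresholds: QCThresholds = QCThresholds(),
    mito_pattern: str = DEFAULT_MITO_PATTERN,
) -> tuple[ExpressionMatrix, QCReport]:
    """Filter cells then genes on the QC thresholds.

    Raises if no cell or no gene survives, reporting per-rule counts in the
    exception message.
    """
    if matrix.layer != "counts":
        raise ValueError("cell QC is defined on the counts layer")
    arr = matrix.values.to_numpy(dtype=float)
    cells = np.asarray(matrix.sample_ids)
    genes = np.asarray(matrix.gene_ids)

    detected = (arr > 0).sum(axis=0)  # genes detected per cell
    mito_mask = np.fromiter((re.search(mito_pattern, g) is not None for g in genes),
                            dtype=bool, count=len(genes))
    totals = arr.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, arr[mito_mask].sum(axis=0) / totals, 0.0)

    lo, hi = thresholds.genes_per_cell_range
    lo = max(lo, thresholds.min_features_per_cell)
    fail_min = detected < lo
    fail_max = detected > hi
    fail_mito = mito_frac >= thresholds.max_mito_fraction  # strict "< 0.05" pass rule
    keep_cells = ~(fail_min | fail_max | fail_mito)

    report = QCReport(
        n_cells_in=len(cells), n_cells_out=int(keep_cells.sum()),
        n_genes_in=len(genes), n_genes_out=0,
        failed_min_features=cells[fail_min].tolist(),
        failed_max_features=cells[fail_max].tolist(),
        failed_mito=cells[fail_mito].tolist(),
        removed_cells=cells[~keep_cells].tolist(),
    )
    if not keep_cells.any():
        raise ValueError(f"all cells removed by QC: {report.to_dict()}")

    sub = arr[:, keep_cells]
    gene_cells = (sub > 0).sum(axis=1)
    keep_genes = gene_cells >= thresholds.min_cells_per_gene
    report.removed_genes = genes[~keep_genes].tolist()
    report.n_genes_out = int(keep_genes.sum())
    if not keep_genes.any():
        raise ValueError(f"all genes removed by QC: {report.to_dict()}")

    filtered = ExpressionMatrix(
        pd.DataFrame(sub[keep_genes], index=genes[keep_genes],
                     columns=cells[keep_cells]),
        layer="counts",
    )
    return filtered, report


def find_cluster_markers(
    matrix: ExpressionMatrix,
    cluster_labels: Mapping[str, str] | pd.Series,
    criteria: MarkerCriteria = MarkerCriteria(),
) -> pd.DataFrame:
    """One-vs-rest marker genes per cluster.

    Counts are log2-transformed with pseudocount 1 for testing; the fold
    change is log2((mean_in + 1) / (mean_out + 1)) on the (normalized or
    raw) expression scale. Clusters with fewer than 3 cells are skipped
    with a warning. Rows failing any criterion are excluded; BH adjustment
    is applied within each cluster.
    """
    labels = pd.Series(cluster_labels).reindex(matrix.sample_ids)
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    uniq = sorted(labels.unique().tolist())
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")

    arr = matrix.values.to_numpy(dtype=float)
    if matrix.layer == "counts":
        test_arr = np.log2(arr + 1.0)
    else:
        test_arr = arr
    genes = np.asarray(matrix.gene_ids)

    frames = []
    for cl in uniq:
        mask_in = (labels == cl).to_numpy()
        if mask_in.sum() < 3:
            logger.warning("cluster %s has <3 cells; skipped", cl)
            continue
        mask_out = ~mask_in
        pct_in = (arr[:, mask_in] > 0).mean(axis=1)
        pct_out = (arr[:, mask_out] > 0).mean(axis=1)
        mean_in = arr[:, mask_in].mean(axis=1)
        mean_out = arr[:, mask_out].mean(axis=1)
        log_fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))

        res = stats.mannwhitneyu(test_arr[:, mask_in], test_arr[:, mask_out],
                                 axis=1, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        pval = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
        padj = bh_adjust(pval)
        keep = ((pct_in >= criteria.min_pct)
                & (log_fc >= criteria.min_log_fc)
                & (padj < criteria.adjusted_p_max))
        frames.append(pd.DataFrame({
            "gene": genes[keep], "cluster": cl,
            "pct_in": pct_in[keep], "pct_out": pct_out[keep],
            "log_fc": log_fc[keep], "pval": pval[keep], "padj": padj[keep],
        }))
    if not frames:
        raise ValueError("no cluster had enough cells for marker detection")
    return pd.concat(frames, ignore_index=True)
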