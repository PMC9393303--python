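"""Differential expression on count matrices.

Normalization is the median-of-ratios size-factor scheme: each sample's
factor is the median, over genes expressed in every sample, of that
sample's count divided by the gene's geometric mean across samples. The
two-group test is a Wilcoxon rank-sum on normalized counts (tie-corrected
normal approximation), with log2 fold changes computed on pseudocounted
group means and Benjamini-Hochberg adjustment. A gene is called significant
when |log2FC| >= 1.0 and adjusted p < 0.05 (the defaults).

Multi-group comparisons use one-way ANOVA with Bonferroni-multiplied
pairwise t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def size_factors(counts: ExpressionMatrix, rescale_geomean: bool = False) -> pd.Series:
    """Median-of-ratios size factors per sample.

    Only genes with nonzero counts in every sample contribute (the
    geometric mean of a zero row is zero). ``rescale_geomean`` divides the
    factors by their own geometric mean so normalized library sizes are
    centred at 1.
    """
    if counts.layer != "counts":
        raise ValueError("size factors are defined on the counts layer")
    arr = counts.values.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = arr[all_positive]
    log_geo_mean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo_mean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    if rescale_geomean:
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize_counts(counts: ExpressionMatrix,
                     factors: pd.Series | None = None) -> ExpressionMatrix:
    """Divide each sample's counts by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    normed = counts.values / factors.reindex(counts.sample_ids).to_numpy()
    return ExpressionMatrix(normed, layer="normalized")


@dataclass
class DEResult:
    """Per-gene two-group comparison results."""

    table: pd.DataFrame  # mean_a, mean_b, log2fc, pval, padj, significant
    group_a: str
    group_b: str
    lfc_min: float
    alpha: float
    n_low_expression_removed: int

    @property
    def significant_genes(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def differential_expression(
    counts: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    min_mean_count: float = 1.0,
) -> DEResult:
    """Two-group differential expression with fold-change and FDR gates.

    ``groups`` maps sample ID to one of exactly two labels; the log2 fold
    change is log2((mean_A + 1) / (mean_B + 1)) with A, B the labels in
    sorted order. Genes whose mean normalized count across all samples is
    below ``min_mean_count`` are removed before testing.
    """
    groups = pd.Series(groups)
    missing = [s for s in counts.sample_ids if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group label: {missing[:5]}")
    groups = groups.reindex(counts.sample_ids)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    a, b = labels
    mask_a = (groups == a).to_numpy()
    mask_b = (groups == b).to_numpy()
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs at least 3 samples")

    normed = normalize_counts(counts).values.to_numpy(dtype=float)
    keep = normed.mean(axis=1) >= min_mean_count
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("low-expression filter removed %d gene(s)", n_removed)
    normed = normed[keep]
    gene_ids = np.asarray(counts.gene_ids)[keep]
    if normed.shape[0] == 0:
        raise ValueError("no genes left after the low-expression filter")

    mean_a = normed[:, mask_a].mean(axis=1)
    mean_b = normed[:, mask_b].mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    res = stats.mannwhitneyu(normed[:, mask_a], normed[:, mask_b],
                             axis=1, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    pval = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
    padj = bh_adjust(pval)
    significant = (np.abs(log2fc) >= lfc_min) & (padj < alpha)

    table = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc,
        "pval": pval, "padj": padj, "significant": significant,
    }, index=pd.Index(gene_ids, name="gene"))
    return DEResult(table=table, group_a=a, group_b=b, lfc_min=lfc_min,
                    alpha=alpha, n_low_expression_removed=n_removed)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def anova_bonferroni(
    values: Sequence[float] | np.ndarray,
    groups: Sequence[str] | np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t-tests.

    Returns (F, p, pairwise table); each pairwise two-sample t-test p-value
    is multiplied by the number of pairs and clipped at 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 3:
        raise ValueError("ANOVA comparison needs at least 3 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 values")
    grand = np.concatenate(samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    ssb = sum(len(s) * (s.mean() - grand.mean()) ** 2 for s in samples)
    if ssw == 0:
        if ssb == 0:
            raise ValueError("all values identical: F statistic undefined")
        f_stat, p = np.inf, 0.0
    else:
        f_stat, p = stats.f_oneway(*samples)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            t, praw = stats.ttest_ind(samples[i], samples[j])
            p_bonf = min(float(praw) * n_pairs, 1.0)
            rows.append({"group_1": labels[i], "group_2": labels[j],
                         "t": float(t), "pval": float(praw),
                         "p_bonferroni": p_bonf,
                         "significant": p_bonf < alpha})
    return float(f_stat), float(p), pd.DataFrame(rows)
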