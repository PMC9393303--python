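"""Gene-set statistics: single-sample enrichment (ssGSEA), pre-ranked GSEA
with a permutation null, and hypergeometric over-representation.

The single-sample enrichment score follows the rank-weighted ECDF-difference
construction: within each sample, genes are ranked by expression (average
ranks on ties) and the score for a set S is the integrated difference

    ES = sum_i [ P_in^w(i) - P_out(i) ]

taken over the gene list ordered by decreasing expression, where P_in^w
accumulates rank^tau over in-set genes (normalized by the in-set total) and
P_out steps uniformly over out-of-set genes. The score depends on the
expression values only through their within-sample ranks, so any monotone
per-sample transform of the data leaves it unchanged.

``normalize=True`` rescales the whole set-by-sample table by its global
range (max - min of the raw scores), which preserves the ordering of scores
within and across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.25


@dataclass
class EnrichmentScores:
    """Set-by-sample enrichment score table."""

    scores: pd.DataFrame  # sets in rows, samples in columns
    normalized: bool
    tau: float

    @property
    def set_names(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.columns.tolist()


def _sample_ranks(expr: np.ndarray) -> np.ndarray:
    """Within-sample ranks, ascending, average on ties (1..N)."""
    return stats.rankdata(expr, method="average")


def _es_one_sample(ranks: np.ndarray, order: np.ndarray, hit: np.ndarray,
                   tau: float) -> float:
    """Integrated weighted-ECDF difference for one sample and one set.

    ``order`` indexes genes by decreasing expression; ``hit`` marks set
    membership in gene order (unpermuted).
    """
    h = hit[order]
    w = ranks[order] ** tau
    w_in = np.where(h, w, 0.0)
    denom_in = w_in.sum()
    n_out = len(ranks) - int(h.sum())
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(~h) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection | Sequence[GeneSet],
    tau: float = DEFAULT_TAU,
    normalize: bool = True,
    min_set_size: int = 2,
) -> EnrichmentScores:
    """Per-sample single-sample enrichment scores for each gene set.

    Sets with fewer than ``min_set_size`` genes mapped onto the matrix are
    skipped with a warning. A sample whose expression is constant across
    all genes has no usable ranking and is an error.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    genes = matrix.gene_ids
    values = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    if n_genes < 2:
        raise ValueError("need at least 2 genes to rank")

    for j, sid in enumerate(matrix.sample_ids):
        col = values[:, j]
        if np.all(col == col[0]):
            raise ValueError(f"sample {sid!r} has constant expression; ranks undefined")

    gene_index = {g: i for i, g in enumerate(genes)}
    usable: list[tuple[str, np.ndarray]] = []
    for s in sets:
        mapped = s.intersect(genes)
        if len(mapped) < min_set_size:
            logger.warning("set %s: only %d gene(s) mapped (<%d); skipped",
                           s.name, len(mapped), min_set_size)
            continue
        if len(mapped) == n_genes:
            raise ValueError(f"set {s.name!r} covers every gene; no out-of-set genes")
        hit = np.zeros(n_genes, dtype=bool)
        hit[[gene_index[g] for g in mapped]] = True
        usable.append((s.name, hit))
    if not usable:
        raise ValueError("no gene set had enough mapped genes")

    out = np.empty((len(usable), n_samples), dtype=float)
    for j in range(n_samples):
        ranks = _sample_ranks(values[:, j])
        # Deterministic order among ties: stable sort by decreasing rank.
        order = np.argsort(-ranks, kind="stable")
        for i, (_, hit) in enumerate(usable):
            out[i, j] = _es_one_sample(ranks, order, hit, tau)

    df = pd.DataFrame(out, index=[name for name, _ in usable],
                      columns=matrix.sample_ids)
    if normalize:
        span = float(df.to_numpy().max() - df.to_numpy().min())
        if span > 0:
            df = df / span
    return EnrichmentScores(scores=df, normalized=normalize, tau=tau)


class SSGSEAScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: samples-by-genes frame in, samples-by-sets
    enrichment scores out.

    The score is stateless (each sample is ranked on its own), so ``fit``
    only records the feature names.
    """

    def __init__(self, sets: GeneSetCollection | Sequence[GeneSet] = (),
                 tau: float = DEFAULT_TAU, normalize: bool = True):
        self.sets = sets
        self.tau = tau
        self.normalize = normalize

    def fit(self, X: pd.DataFrame, y=None) -> "SSGSEAScorer":
        X = self._check_frame(X)
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "feature_names_in_"):
            raise RuntimeError("SSGSEAScorer is not fitted")
        X = self._check_frame(X)
        matrix = ExpressionMatrix(X.T.astype(float), layer="normalized")
        es = ssgsea(matrix, self.sets, tau=self.tau, normalize=self.normalize)
        return es.scores.T

    @staticmethod
    def _check_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a samples-by-genes DataFrame with gene-ID columns")
        return X


# ---------------------------------------------------------------------------
# Pre-ranked GSEA


def _running_es(abs_scores: np.ndarray, hit: np.ndarray) -> float:
    """Signed maximum deviation of the weighted running sum for one hit mask
    over a score-ordered gene list."""
    denom = abs_scores[hit].sum()
    n_out = hit.size - int(hit.sum())
    if denom == 0 or n_out == 0:
        return 0.0
    inc = np.where(hit, abs_scores / denom, -1.0 / n_out)
    running = np.cumsum(inc)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    ranking: Mapping[str, float] | pd.Series,
    sets: GeneSetCollection | Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-label permutation null.

    For each set, the enrichment score is the maximum deviation from zero of
    the weighted running sum over the gene list ordered by decreasing score
    (hits increment by normalized |score|, misses decrement uniformly). The
    null is built by permuting set membership over the gene labels; NES is
    ES divided by the mean |permuted ES| of matching sign, and the nominal p
    is the matching-sign permutation tail, Benjamini-Hochberg adjusted
    across sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    series = pd.Series(ranking, dtype=float)
    if series.index.has_duplicates:
        raise ValueError("ranking has duplicate gene IDs")
    if not np.isfinite(series.to_numpy()).all():
        raise ValueError("ranking scores must be finite")
    order = np.argsort(-series.to_numpy(), kind="stable")
    genes = series.index.to_numpy()[order]
    abs_scores = np.abs(series.to_numpy()[order])
    n = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    rows = []
    for s in sets:
        mapped = [g for g in s.genes if g in gene_pos]
        if not mapped:
            logger.warning("set %s: no genes in the ranking; skipped", s.name)
            continue
        k = len(mapped)
        if k == n:
            logger.warning("set %s covers the whole ranking; skipped", s.name)
            continue
        hit = np.zeros(n, dtype=bool)
        hit[[gene_pos[g] for g in mapped]] = True
        es = _running_es(abs_scores, hit)

        perm_es = _permutation_es(abs_scores, k, n_perm, rng)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if same_sign.size == 0:
            nes = np.nan
            p = 1.0 / (n_perm + 1)
        else:
            mean_mag = np.abs(same_sign).mean()
            nes = es / mean_mag if mean_mag > 0 else np.nan
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
        rows.append({"set": s.name, "size": k, "es": es, "nes": nes,
                     "pval": float(p), "n_perm": n_perm})
    if not rows:
        raise ValueError("no gene set overlapped the ranking")
    result = pd.DataFrame(rows).set_index("set")
    from .de import bh_adjust  # local import to avoid a cycle
    result["padj"] = bh_adjust(result["pval"].to_numpy())
    return result


def _permutation_es(abs_scores: np.ndarray, k: int, n_perm: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Vectorized gene-label permutation null: ES for ``n_perm`` random
    k-subsets of positions."""
    n = abs_scores.size
    # random k-subsets via argpartition of uniform keys (rows independent)
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, idx, True, axis=1)
    denom = hits @ abs_scores  # per-perm in-set weight total
    denom[denom == 0] = np.inf
    inc = np.where(hits, abs_scores[None, :] / denom[:, None], -1.0 / (n - k))
    running = np.cumsum(inc, axis=1)
    at = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), at]


# ---------------------------------------------------------------------------
# Over-representation


def hypergeom_ora(selected: frozenset[str] | set[str],
                  annotation: GeneSet | frozenset[str] | set[str],
                  universe: frozenset[str] | set[str]) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation test.

    Returns the overlap size and P(overlap >= observed) when ``len(selected)``
    genes are drawn from ``universe`` without replacement against the
    annotation set.
    """
    ann = annotation.genes if isinstance(annotation, GeneSet) else frozenset(annotation)
    selected = frozenset(selected)
    universe = frozenset(universe)
    if not selected <= universe:
        raise ValueError("selected genes are not a subset of the universe")
    extra = ann - universe
    if extra:
        logger.warning("annotation has %d gene(s) outside the universe; restricted", len(extra))
        ann = ann & universe
    overlap = len(selected & ann)
    m, big_k, small_n = len(universe), len(ann), len(selected)
    p = float(stats.hypergeom.sf(overlap - 1, m, big_k, small_n))
    return overlap, min(p, 1.0)
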