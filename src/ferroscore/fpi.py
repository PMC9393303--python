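"""Ferroptosis potential index (FPI).

FPI is computed per sample as the difference between two single-sample
enrichment scores: ES over the positive ferroptosis regulators minus ES
over the negative regulators. Because the underlying score is rank-based,
FPI is invariant to any per-sample monotone transform of expression and is
exactly antisymmetric under swapping the two regulator panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .enrichment import DEFAULT_TAU, ssgsea
from .io import ExpressionMatrix, GeneSetCollection, RegulatorPanel, default_regulator_panel


@dataclass
class FpiResult:
    """Per-sample positive/negative enrichment scores and their difference."""

    table: pd.DataFrame  # columns: es_pos, es_neg, fpi [+ group, stratum]
    tau: float
    normalized: bool

    @property
    def fpi(self) -> pd.Series:
        return self.table["fpi"]

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()


def compute_fpi(
    matrix: ExpressionMatrix,
    panel: RegulatorPanel | None = None,
    tau: float = DEFAULT_TAU,
    normalize: bool = True,
    groups: pd.Series | None = None,
) -> FpiResult:
    """FPI per sample: ES(positive regulators) - ES(negative regulators).

    At least 2 genes of each panel side must map onto the matrix; otherwise
    the error lists the missing genes.
    """
    if panel is None:
        panel = default_regulator_panel()
    present = set(matrix.gene_ids)
    for side in (panel.positive, panel.negative):
        mapped = side.genes & present
        if len(mapped) < 2:
            missing = sorted(side.genes - present)
            raise ValueError(
                f"regulator set {side.name!r}: only {len(mapped)} gene(s) mapped "
                f"(need >=2); missing: {missing}"
            )
    es = ssgsea(matrix, GeneSetCollection([panel.positive, panel.negative]),
                tau=tau, normalize=normalize)
    table = pd.DataFrame({
        "es_pos": es.scores.loc[panel.positive.name],
        "es_neg": es.scores.loc[panel.negative.name],
    })
    table["fpi"] = table["es_pos"] - table["es_neg"]
    table.index.name = "sample"
    if groups is not None:
        table["group"] = pd.Series(groups).reindex(table.index)
    return FpiResult(table=table, tau=tau, normalized=normalize)


def compare_fpi_groups(fpi: FpiResult | pd.Series, groups: pd.Series) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of FPI between two groups.

    Uses the tie-corrected normal approximation (identical groups give
    p = 1 exactly). Returns the statistic, p-value and group medians.
    """
    values = fpi.fpi if isinstance(fpi, FpiResult) else pd.Series(fpi)
    groups = pd.Series(groups).reindex(values.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = sorted(groups.unique().tolist())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    a = values[groups == labels[0]].to_numpy(dtype=float)
    b = values[groups == labels[1]].to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return {
        "statistic": float(res.statistic),
        "pval": float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
        "groups": labels,
        "medians": {labels[0]: float(np.median(a)), labels[1]: float(np.median(b))},
        "n": {labels[0]: len(a), labels[1]: len(b)},
    }


def split_high_low(
    scores: pd.Series,
    method: str = "median",
    survival=None,
    min_stratum_frac: float = 0.10,
) -> pd.Series:
    """Split samples into ``high``/``low`` strata on a score.

    ``median`` labels scores strictly above the median high and the rest
    (including median ties) low. ``maxstat`` scans candidate cutpoints and
    picks the one maximizing the two-group log-rank statistic, under the
    constraint that each stratum keeps at least ``min_stratum_frac`` of the
    samples; it requires a :class:`~ferroscore.io.SurvivalTable` aligned by
    sample ID.
    """
    scores = pd.Series(scores, dtype=float)
    if len(scores) < 4:
        raise ValueError("need at least 4 samples to split")
    if scores.nunique() == 1:
        raise ValueError("all scores identical: no split exists")

    if method == "median":
        cut = float(scores.median())
        labels = np.where(scores.to_numpy() > cut, "high", "low")
        return pd.Series(labels, index=scores.index, name="stratum")
    if method == "maxstat":
        if survival is None:
            raise ValueError("maxstat split requires a survival table")
        return _maxstat_split(scores, survival, min_stratum_frac)
    raise ValueError(f"unknown split method {method!r}")


def _maxstat_split(scores: pd.Series, survival, min_frac: float) -> pd.Series:
    from .survival import logrank_test  # deferred: survival imports nothing from here

    order = survival.data.set_index("sample").reindex(scores.index.astype(str))
    if order["time"].isna().any():
        raise ValueError("survival table does not cover all scored samples")
    time = order["time"].to_numpy(dtype=float)
    event = order["event"].to_numpy(dtype=int)
    vals = scores.to_numpy(dtype=float)
    n = len(vals)
    lo_rank = int(np.ceil(min_frac * n))
    candidates = np.unique(vals)[:-1]  # cut at value -> high is "> cut"
    best_cut, best_stat = None, -np.inf
    for cut in candidates:
        high = vals > cut
        if high.sum() < lo_rank or (~high).sum() < lo_rank:
            continue
        chi2, _ = logrank_test(time, event, high)
        if chi2 > best_stat:
            best_stat, best_cut = chi2, cut
    if best_cut is None:
        raise ValueError("no cutpoint satisfies the minimum stratum size")
    labels = np.where(vals > best_cut, "high", "low")
    out = pd.Series(labels, index=scores.index, name="stratum")
    out.attrs["cutpoint"] = float(best_cut)
    out.attrs["statistic"] = float(best_stat)
    return out


class FPIScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: samples-by-genes frame in, one-column FPI
    frame out. Stateless; ``fit`` records feature names only."""

    def __init__(self, panel: RegulatorPanel | None = None,
                 tau: float = DEFAULT_TAU, normalize: bool = True):
        self.panel = panel
        self.tau = tau
        self.normalize = normalize

    def fit(self, X: pd.DataFrame, y=None) -> "FPIScorer":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a samples-by-genes DataFrame")
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "feature_names_in_"):
            raise RuntimeError("FPIScorer is not fitted")
        matrix = ExpressionMatrix(X.T.astype(float), layer="normalized")
        result = compute_fpi(matrix, panel=self.panel, tau=self.tau,
                             normalize=self.normalize)
        return result.table[["fpi"]]
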