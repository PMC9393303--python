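"""Immunophenoscore (IPS).

The immunophenoscore summarizes a sample's tumor immunophenotype from four
gene categories: MHC-related molecules (antigen presentation), checkpoints
and immunomodulators (CP), effector cells (EC) and suppressor cells (SC).
Each gene is z-scored across the cohort; a component score is the weighted
mean of its member-gene z-scores (weights signed, from the gene table); a
category score is the unweighted mean of its component scores; the averaged
Z (AZ) is the mean of the four category scores; and the 0-10 IPS maps AZ
linearly (0 at AZ <= 0, 10 at AZ >= 3, rounded between).

The gene/weight table is user-supplied (it belongs to the original
immunophenogram publication, not to this package); the test suite ships a
small synthetic table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import IPS_CATEGORIES, ExpressionMatrix, validate_ips_table

logger = logging.getLogger(__name__)


@dataclass
class IpsResult:
    """Per-sample category scores, averaged Z, and 0-10 IPS."""

    table: pd.DataFrame  # columns MHC, CP, EC, SC, AZ, IPS

    @property
    def az(self) -> pd.Series:
        return self.table["AZ"]

    @property
    def ips(self) -> pd.Series:
        return self.table["IPS"]


def az_to_ips(az: np.ndarray | float) -> np.ndarray:
    """Map averaged Z to the integer 0-10 immunophenoscore: 0 at AZ <= 0,
    10 at AZ >= 3, linear with half-up rounding between."""
    az = np.asarray(az, dtype=float)
    scaled = np.floor(10.0 * az / 3.0 + 0.5)  # half-up, not banker's
    return np.clip(scaled, 0, 10).astype(int)


class IPSScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: samples-by-genes frame in, per-sample
    MHC/CP/EC/SC/AZ/IPS frame out.

    ``fit`` learns the cohort gene means and standard deviations used for
    z-scoring, so new samples can be scored against a reference cohort.
    """

    def __init__(self, gene_table: pd.DataFrame | None = None,
                 aggregate: str = "mean", ddof: int = 1):
        self.gene_table = gene_table
        self.aggregate = aggregate
        self.ddof = ddof

    def fit(self, X: pd.DataFrame, y=None) -> "IPSScorer":
        X = self._check(X)
        table = validate_ips_table(self.gene_table)
        mapped = table[table["gene"].isin(X.columns)]
        dropped = len(table) - len(mapped)
        if dropped:
            logger.info("IPS table: %d row(s) with genes absent from matrix dropped", dropped)
        for cat in IPS_CATEGORIES:
            if (mapped["category"] == cat).sum() == 0:
                raise ValueError(f"IPS category {cat} has no mapped genes")
        if X.shape[0] < 3:
            raise ValueError("z-scoring needs at least 3 samples")
        genes = mapped["gene"].unique().tolist()
        sub = X[genes].astype(float)
        self.mapped_table_ = mapped.reset_index(drop=True)
        self.gene_means_ = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=self.ddof)
        zero_var = sd[sd == 0].index.tolist()
        if zero_var:
            logger.warning("%d zero-variance gene(s); their z-scores set to 0", len(zero_var))
        self.gene_sds_ = sd
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "gene_means_"):
            raise RuntimeError("IPSScorer is not fitted")
        X = self._check(X)
        table = self.mapped_table_
        genes = self.gene_means_.index
        missing = [g for g in genes if g not in X.columns]
        if missing:
            raise ValueError(f"matrix lacks fitted IPS genes: {missing[:5]}")
        sd = self.gene_sds_.to_numpy()
        safe_sd = np.where(sd > 0, sd, 1.0)
        z = (X[genes].astype(float) - self.gene_means_) / safe_sd
        z.loc[:, sd == 0] = 0.0

        # component score = mean over member rows of weight * z
        weighted = pd.DataFrame(index=X.index)
        comp_cat: dict[tuple[str, str], pd.Series] = {}
        for (cat, comp), rows in table.groupby(["category", "component"]):
            wz = z[rows["gene"].to_numpy()].to_numpy() * rows["weight"].to_numpy()[None, :]
            comp_cat[(cat, comp)] = pd.Series(wz.mean(axis=1), index=X.index)
        cat_scores = {}
        for cat in IPS_CATEGORIES:
            members = [s for (c, _), s in comp_cat.items() if c == cat]
            cat_scores[cat] = pd.concat(members, axis=1).mean(axis=1)
        out = pd.DataFrame(cat_scores)[list(IPS_CATEGORIES)]
        if self.aggregate == "mean":
            out["AZ"] = out[list(IPS_CATEGORIES)].mean(axis=1)
        elif self.aggregate == "sum":
            out["AZ"] = out[list(IPS_CATEGORIES)].sum(axis=1)
        else:
            raise ValueError("aggregate must be 'mean' or 'sum'")
        out["IPS"] = az_to_ips(out["AZ"].to_numpy())
        out.index.name = "sample"
        return out

    @staticmethod
    def _check(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a samples-by-genes DataFrame with gene-ID columns")
        return X


def compute_ips(matrix: ExpressionMatrix, gene_table: pd.DataFrame,
                aggregate: str = "mean") -> IpsResult:
    """Score a cohort against itself: z-scores use this matrix's own means
    and standard deviations."""
    scorer = IPSScorer(gene_table=gene_table, aggregate=aggregate)
    frame = scorer.fit(matrix.values.T).transform(matrix.values.T)
    return IpsResult(table=frame)
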