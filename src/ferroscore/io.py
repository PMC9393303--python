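"""Core data types and readers/writers.

The pipeline exchanges four kinds of artifacts: gene-by-sample expression
matrices (dense TSV or MatrixMarket triplet directories), gene sets (GMT),
immunophenoscore gene/weight tables (TSV), and survival tables (TSV).
Everything is UTF-8 plain text.

Gene and sample identifiers are matched exactly and case-sensitively by
default; an opt-in uppercase fold is available where sets are mapped onto
matrices, because silent case-folding hides mapping bugs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

LAYERS = ("counts", "normalized", "log2")

#: Ferroptosis driver genes: promote lipid-peroxide accumulation.
POSITIVE_REGULATORS = (
    "LPCAT3", "ACSL4", "NCOA4", "ALOX15", "NFE2L2", "NOX1",
    "NOX3", "NOX4", "NOX5", "GPX4", "SLC3A2", "SLC7A11",
)
#: Ferroptosis suppressor genes (mevalonate / CoQ10 axis).
NEGATIVE_REGULATORS = ("FDFT1", "HMGCR", "COQ10A", "COQ10B")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, gene_ids: Sequence[str], uppercase: bool = False) -> list[str]:
        """Members present in ``gene_ids``, in the order of ``gene_ids``.

        Genes absent from the matrix are dropped with a logged count, never
        an error.
        """
        members = self.genes
        if uppercase:
            members = frozenset(g.upper() for g in members)
            hits = [g for g in gene_ids if g.upper() in members]
        else:
            hits = [g for g in gene_ids if g in members]
        n_missing = len(members) - len(hits)
        if n_missing > 0:
            logger.info("gene set %s: %d member(s) absent from matrix", self.name, n_missing)
        return hits


class GeneSetCollection:
    """Ordered, name-keyed collection of :class:`GeneSet`."""

    def __init__(self, sets: Sequence[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene set name: {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)


@dataclass(frozen=True)
class RegulatorPanel:
    """Positive/negative ferroptosis regulator gene lists.

    The default panel ships the 16 genes of the published regulator lists
    (12 positive drivers, 4 negative suppressors).
    """

    positive: GeneSet
    negative: GeneSet

    def __post_init__(self) -> None:
        if self.positive.genes & self.negative.genes:
            overlap = sorted(self.positive.genes & self.negative.genes)
            raise ValueError(f"positive and negative regulators overlap: {overlap}")

    def swapped(self) -> "RegulatorPanel":
        return RegulatorPanel(positive=self.negative, negative=self.positive)


def default_regulator_panel() -> RegulatorPanel:
    """The 16-gene ferroptosis regulator panel (12 positive, 4 negative)."""
    return RegulatorPanel(
        positive=GeneSet("POSITIVE", frozenset(POSITIVE_REGULATORS),
                         "ferroptosis driver genes"),
        negative=GeneSet("NEGATIVE", frozenset(NEGATIVE_REGULATORS),
                         "ferroptosis suppressor genes"),
    )


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a layer tag.

    ``values`` is a pandas DataFrame indexed by gene ID with sample IDs as
    columns. The ``counts`` layer must be nonnegative; no layer may contain
    missing or non-finite values.
    """

    values: pd.DataFrame
    layer: str = "counts"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains NaN or infinite values")
        if self.layer == "counts" and (arr < 0).any():
            raise ValueError("counts layer contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], layer=self.layer)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], layer=self.layer)


@dataclass
class SurvivalTable:
    """Per-sample follow-up: time, event indicator, optional covariates.

    ``endpoint`` labels which outcome the times describe (overall survival,
    progression-free interval, or disease-specific survival); it is carried
    as a label only.
    """

    data: pd.DataFrame  # columns: sample, time, event, [endpoint], covariates...
    endpoint: str = "OS"

    REQUIRED = ("sample", "time", "event")
    ENDPOINTS = ("OS", "PFI", "DSS")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"survival table missing columns: {missing}")
        if self.endpoint not in self.ENDPOINTS:
            raise ValueError(f"endpoint must be one of {self.ENDPOINTS}")
        if self.data["sample"].duplicated().any():
            raise ValueError("duplicate sample IDs in survival table")
        t = self.data["time"].to_numpy(dtype=float)
        if not np.isfinite(t).all() or (t < 0).any():
            raise ValueError("survival times must be finite and nonnegative")
        e = self.data["event"].to_numpy()
        if not np.isin(e, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample"].astype(str).tolist()

    def covariate(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"no covariate column {name!r}")
        return self.data[name].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated line per set (name, description,
    genes...). Duplicate genes within a line are deduplicated with a logged
    warning; duplicate set names and malformed lines are errors.
    """
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning(
                    "%s: line %d: set %s has %d duplicate gene entries (deduplicated)",
                    path, lineno, name, len(genes) - len(unique),
                )
            try:
                collection.add(GeneSet(name, frozenset(unique), description))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return collection


def write_gmt(sets: GeneSetCollection | Sequence[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def panel_to_collection(panel: RegulatorPanel) -> GeneSetCollection:
    return GeneSetCollection([panel.positive, panel.negative])


def panel_from_collection(sets: GeneSetCollection) -> RegulatorPanel:
    """Build a regulator panel from a GMT-backed collection with sets named
    POSITIVE and NEGATIVE."""
    if "POSITIVE" not in sets or "NEGATIVE" not in sets:
        raise ValueError("panel GMT must contain sets named POSITIVE and NEGATIVE")
    return RegulatorPanel(positive=sets["POSITIVE"], negative=sets["NEGATIVE"])


# ---------------------------------------------------------------------------
# Expression matrices

def read_matrix(path: str | os.PathLike, layer: str = "counts") -> ExpressionMatrix:
    """Read an expression matrix from a dense TSV (genes in rows, header of
    sample IDs) or an MTX triplet directory (matrix.mtx + genes.tsv +
    barcodes.tsv)."""
    path = os.fspath(path)
    if os.path.isdir(path):
        return _read_mtx_dir(path, layer)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing values")
    return ExpressionMatrix(df.astype(float), layer=layer)


def _read_mtx_dir(path: str, layer: str) -> ExpressionMatrix:
    mtx_path = os.path.join(path, "matrix.mtx")
    genes_path = os.path.join(path, "genes.tsv")
    barcodes_path = os.path.join(path, "barcodes.tsv")
    for p in (mtx_path, genes_path, barcodes_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    mat = scipy.io.mmread(mtx_path)
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"{path}: matrix shape {dense.shape} does not match "
            f"{len(genes)} genes x {len(barcodes)} barcodes"
        )
    df = pd.DataFrame(dense, index=genes, columns=barcodes)
    return ExpressionMatrix(df, layer=layer)


def write_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write a dense TSV. Integer-valued count matrices are written as
    integers so that round-trips are bit-exact."""
    df = matrix.values
    arr = df.to_numpy()
    if matrix.layer == "counts" and np.allclose(arr, np.round(arr)):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="gene")


def write_mtx_dir(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    os.makedirs(path, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.values.to_numpy())
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sparse)
    pd.Series(matrix.gene_ids).to_csv(
        os.path.join(path, "genes.tsv"), sep="\t", header=False, index=False)
    pd.Series(matrix.sample_ids).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# IPS gene/weight tables

IPS_CATEGORIES = ("MHC", "CP", "EC", "SC")


def read_ips_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an immunophenoscore gene table: TSV with columns
    gene, category (MHC/CP/EC/SC), component, weight (signed, nonzero)."""
    df = pd.read_csv(path, sep="\t")
    return validate_ips_table(df)


def validate_ips_table(df: pd.DataFrame) -> pd.DataFrame:
    required = ["gene", "category", "component", "weight"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"IPS table missing columns: {missing}")
    bad_cat = sorted(set(df["category"]) - set(IPS_CATEGORIES))
    if bad_cat:
        raise ValueError(f"IPS table has unknown categories: {bad_cat}")
    w = df["weight"].to_numpy(dtype=float)
    if not np.isfinite(w).all() or (w == 0).any():
        raise ValueError("IPS weights must be finite and nonzero")
    if df.duplicated(subset=["gene", "component"]).any():
        raise ValueError("IPS table has duplicate (gene, component) pairs")
    return df


def write_ips_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_ips_table(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Survival tables

def read_survival(path: str | os.PathLike, endpoint: str | None = None) -> SurvivalTable:
    """Read a survival TSV with columns sample, time, event and optional
    covariate columns. An ``endpoint`` column, if present, must be uniform;
    the ``endpoint`` argument overrides it."""
    df = pd.read_csv(path, sep="\t")
    if endpoint is None:
        if "endpoint" in df.columns:
            values = df["endpoint"].unique().tolist()
            if len(values) != 1:
                raise ValueError(f"mixed endpoints in one table: {values}")
            endpoint = str(values[0])
        else:
            endpoint = "OS"
    df = df.drop(columns=[c for c in ("endpoint",) if c in df.columns])
    df["sample"] = df["sample"].astype(str)
    return SurvivalTable(df, endpoint=endpoint)


def write_survival(table: SurvivalTable, path: str | os.PathLike) -> None:
    df = table.data.copy()
    df["endpoint"] = table.endpoint
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
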