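"""Synthetic data with known ground truth.

Three generators stand in for the study's real inputs so every downstream
stage has a recovery test with a known answer:

* negative-binomial count matrices with group structure, planted
  differentially expressed genes (multiplicative, a stated log2 fold
  change) and planted gene-set activity (member means multiplied by an
  effect size in active samples);
* single-cell count matrices with mitochondrially-labeled genes and a
  chosen number of cells planted to violate each QC rule;
* survival tables with event times drawn from an exponential hazard
  lambda0 * exp(beta * score) and independent exponential censoring whose
  rate is solved numerically to hit a requested censoring fraction.

Every generator is a pure function of its configuration (which records the
seed); the same configuration always yields the same output.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SurvivalTable


@dataclass(frozen=True)
class PlantedDE:
    """Genes whose NB mean is multiplied by 2**log2fc in one group."""

    genes: tuple[str, ...]
    log2fc: float
    factor: str = "group"
    group: str = "tumor"


@dataclass(frozen=True)
class PlantedSetActivity:
    """A gene set whose member means are multiplied by ``effect_size`` in
    the active samples (a group label of a factor, or explicit sample IDs)."""

    name: str
    genes: tuple[str, ...]
    effect_size: float
    factor: str = "group"
    group: str | None = "tumor"
    samples: tuple[str, ...] | None = None


@dataclass
class CountSimConfig:
    """Configuration for the bulk NB count generator.

    ``factors`` maps a factor name to per-sample labels; the default is a
    single tumor/normal factor split evenly. ``named_genes`` are placed at
    the top of the gene list (so planted effects can target genes by name,
    e.g. the ferroptosis regulator panel); the rest are filled in as
    G0001, G0002, ...
    """

    n_genes: int = 2000
    n_samples: int = 100
    factors: dict[str, tuple[str, ...]] = field(default_factory=dict)
    named_genes: tuple[str, ...] = ()
    base_mean_range: tuple[float, float] = (5.0, 500.0)
    dispersion: float = 10.0
    de: tuple[PlantedDE, ...] = ()
    set_activity: tuple[PlantedSetActivity, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise ValueError("base_mean_range must be positive and ordered")
        if not self.factors:
            half = self.n_samples // 2
            labels = ("tumor",) * half + ("normal",) * (self.n_samples - half)
            self.factors = {"group": labels}
        for name, labels in self.factors.items():
            if len(labels) != self.n_samples:
                raise ValueError(f"factor {name!r} has {len(labels)} labels, "
                                 f"expected {self.n_samples}")
        if len(self.named_genes) > self.n_genes:
            raise ValueError("more named genes than n_genes")

    @property
    def gene_ids(self) -> list[str]:
        n_auto = self.n_genes - len(self.named_genes)
        width = max(4, len(str(n_auto)))
        return list(self.named_genes) + [f"G{i:0{width}d}" for i in range(1, n_auto + 1)]

    @property
    def sample_ids(self) -> list[str]:
        width = max(3, len(str(self.n_samples)))
        return [f"S{i:0{width}d}" for i in range(1, self.n_samples + 1)]


@dataclass
class GroundTruth:
    """The planted structure behind a simulated dataset."""

    seed: int
    de_genes: dict[str, float] = field(default_factory=dict)
    set_activity: dict[str, list[str]] = field(default_factory=dict)
    qc_fail: dict[str, list[str]] = field(default_factory=dict)
    qc_pass: list[str] = field(default_factory=list)
    beta: float | None = None
    censor_rate: float | None = None

    def failing_cells(self) -> set[str]:
        return {c for cells in self.qc_fail.values() for c in cells}

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _active_mask(effect: PlantedSetActivity | PlantedDE,
                 config: CountSimConfig) -> np.ndarray:
    samples = np.asarray(config.sample_ids)
    if isinstance(effect, PlantedSetActivity) and effect.samples is not None:
        return np.isin(samples, list(effect.samples))
    labels = np.asarray(config.factors[effect.factor])
    return labels == effect.group


def simulate_counts(config: CountSimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw an NB count matrix with the configured planted structure.

    Per-gene base means are log-uniform over ``base_mean_range``; counts are
    NB with size (inverse-dispersion) ``dispersion``, so
    var = mean + mean^2 / dispersion.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = config.gene_ids
    sample_ids = config.sample_ids
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    lo, hi = config.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    mean = np.tile(base[:, None], (1, config.n_samples))

    truth = GroundTruth(seed=config.seed)
    for planted in config.de:
        mask = _active_mask(planted, config)
        rows = [gene_pos[g] for g in planted.genes]
        mean[np.ix_(rows, mask)] *= 2.0 ** planted.log2fc
        for g in planted.genes:
            truth.de_genes[g] = truth.de_genes.get(g, 0.0) + planted.log2fc
    for activity in config.set_activity:
        mask = _active_mask(activity, config)
        rows = [gene_pos[g] for g in activity.genes]
        mean[np.ix_(rows, mask)] *= activity.effect_size
        truth.set_activity[activity.name] = np.asarray(sample_ids)[mask].tolist()

    theta = config.dispersion
    p = theta / (theta + mean)
    counts = rng.negative_binomial(theta, p).astype(np.int64)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), layer="counts")
    return matrix, truth


# ---------------------------------------------------------------------------
# Single-cell QC fixtures


@dataclass
class CellQCSimConfig:
    """Single-cell matrix with planted QC violations.

    Normal cells detect about ``baseline_detected`` genes with a
    mitochondrial count fraction near ``baseline_mito_fraction``; planted
    cells get a mitochondrial fraction of ``high_mito_fraction``, or a
    detected-gene count of ``low_feature_count`` / ``high_feature_count``.
    The three violation groups are disjoint cells.
    """

    n_cells: int = 50
    n_genes: int = 1000
    n_mito_genes: int = 10
    mito_prefix: str = "MT-"
    baseline_detected: int = 600
    baseline_mito_fraction: float = 0.01
    n_high_mito: int = 5
    high_mito_fraction: float = 0.2
    n_low_features: int = 0
    low_feature_count: int = 150
    n_high_features: int = 0
    high_feature_count: int = 20001
    seed: int = 0

    def __post_init__(self) -> None:
        n_planted = self.n_high_mito + self.n_low_features + self.n_high_features
        if n_planted > self.n_cells:
            raise ValueError("requested violations exceed n_cells")
        if self.n_mito_genes + self.baseline_detected > self.n_genes:
            raise ValueError("baseline_detected too large for n_genes")
        if self.n_high_features > 0 and self.high_feature_count > self.n_genes:
            raise ValueError("high_feature_count exceeds n_genes")


def simulate_cells_for_qc(config: CellQCSimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    n_mito = config.n_mito_genes
    mito_genes = [f"{config.mito_prefix}{i}" for i in range(1, n_mito + 1)]
    width = max(4, len(str(config.n_genes)))
    other_genes = [f"GC{i:0{width}d}" for i in range(1, config.n_genes - n_mito + 1)]
    genes = mito_genes + other_genes
    cells = [f"C{i:03d}" for i in range(1, config.n_cells + 1)]

    planted = rng.permutation(config.n_cells)
    hi_mito = set(planted[:config.n_high_mito])
    k = config.n_high_mito
    lo_feat = set(planted[k:k + config.n_low_features])
    k += config.n_low_features
    hi_feat = set(planted[k:k + config.n_high_features])

    arr = np.zeros((len(genes), config.n_cells), dtype=np.int64)
    for j in range(config.n_cells):
        if j in lo_feat:
            # total detected (incl. mito) stays below the target count
            d = max(config.low_feature_count - n_mito, 1)
        elif j in hi_feat:
            d = config.high_feature_count - n_mito
        else:
            d = int(rng.integers(config.baseline_detected - 50,
                                 config.baseline_detected + 51))
        chosen = rng.choice(len(other_genes), size=d, replace=False) + n_mito
        arr[chosen, j] = 1 + rng.poisson(4.0, size=d)
        nonmito_total = arr[n_mito:, j].sum()
        f = config.high_mito_fraction if j in hi_mito else config.baseline_mito_fraction
        mito_total = int(round(f / (1.0 - f) * nonmito_total))
        if mito_total > 0:
            arr[:n_mito, j] = rng.multinomial(mito_total, np.full(n_mito, 1.0 / n_mito))

    truth = GroundTruth(
        seed=config.seed,
        qc_fail={
            "mito_fraction": sorted(cells[j] for j in hi_mito),
            "min_features": sorted(cells[j] for j in lo_feat),
            "max_features": sorted(cells[j] for j in hi_feat),
        },
    )
    failing = truth.failing_cells()
    truth.qc_pass = [c for c in cells if c not in failing]
    matrix = ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=cells),
                              layer="counts")
    return matrix, truth


# ---------------------------------------------------------------------------
# Survival


def _solve_censor_rate(event_rates: np.ndarray, target: float) -> float:
    """Rate of an independent exponential censor such that the expected
    censored fraction, mean_i lc / (lc + li), equals ``target``."""

    def frac(lc: float) -> float:
        return float(np.mean(lc / (lc + event_rates)))

    lo, hi = 1e-12, float(event_rates.max())
    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e18:
            raise RuntimeError("failed to bracket the censoring rate")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival(
    scores: pd.Series | Mapping[str, float],
    beta: float,
    lambda0: float,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> tuple[SurvivalTable, GroundTruth]:
    """Event times from the proportional-hazards model
    T_i ~ Exponential(lambda0 * exp(beta * score_i)) with independent
    exponential censoring tuned to the requested censoring fraction.

    The score is carried along as a covariate column so the table feeds the
    Cox fit directly.
    """
    if lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must lie in [0, 1)")
    scores = pd.Series(scores, dtype=float)
    rng = np.random.default_rng(seed)
    rates = lambda0 * np.exp(beta * scores.to_numpy())
    t_event = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        lc = _solve_censor_rate(rates, censor_rate)
        t_censor = rng.exponential(1.0 / lc, size=len(scores))
        time = np.minimum(t_event, t_censor)
        event = (t_event <= t_censor).astype(int)
    else:
        time, event = t_event, np.ones(len(scores), dtype=int)
    table = SurvivalTable(pd.DataFrame({
        "sample": scores.index.astype(str),
        "time": time,
        "event": event,
        "score": scores.to_numpy(),
    }))
    truth = GroundTruth(seed=seed, beta=beta, censor_rate=censor_rate)
    return table, truth


# ---------------------------------------------------------------------------
# Synthetic immunophenoscore gene table


def synthetic_ips_table(seed: int = 0, genes_per_component: int = 3) -> pd.DataFrame:
    """A small synthetic immunophenogram gene/weight table.

    Mirrors the shape of the real table — four categories (MHC, CP, EC,
    SC), a few components each, signed weights (positive for antigen
    presentation and effector cells, negative for checkpoints and
    suppressor cells) — with synthetic gene names.
    """
    rng = np.random.default_rng(seed)
    layout = {
        "MHC": (("MHC_I", 1.0), ("MHC_II", 1.0)),
        "CP": (("CHECKPOINT_A", -1.0), ("CHECKPOINT_B", -1.0)),
        "EC": (("EFFECTOR_T", 1.0), ("EFFECTOR_NK", 1.0)),
        "SC": (("SUPPRESSOR_TREG", -1.0), ("SUPPRESSOR_MDSC", -1.0)),
    }
    rows = []
    for cat, components in layout.items():
        for comp, sign in components:
            for g in range(1, genes_per_component + 1):
                weight = sign * float(np.round(rng.uniform(0.5, 1.0), 3))
                rows.append({"gene": f"{comp}_G{g}", "category": cat,
                             "component": comp, "weight": weight})
    return pd.DataFrame(rows)
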