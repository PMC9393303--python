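"""End-to-end orchestration of the synthetic ferroptosis-scoring analysis.

A single configuration drives: simulation (or loading) of a bulk count
matrix with planted structure, single-cell QC on a planted-violation cell
matrix, per-sample enrichment scoring, FPI, IPS, two differential
expression contrasts (a tumor/normal factor and a progression-stage factor
standing in for the trajectory-derived contrast), survival analysis on the
FPI, and the correlation/hub-gene integration step.

One global seed fans out to per-stage seeds by fixed offsets so a stage
keeps its stream when other stages are toggled. All outputs are plain text
(TSV/JSON/Newick) written with fixed float formatting, so a rerun with the
same configuration is byte-identical; the manifest records parameters,
per-stage row counts, and SHA-256 digests of every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time as _time
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import qc as qc_mod
from .enrichment import preranked_gsea, ssgsea
from .fpi import compare_fpi_groups, compute_fpi, split_high_low
from .integration import hub_gene_intersection, spearman_matrix
from .io import (ExpressionMatrix, GeneSet, GeneSetCollection, default_regulator_panel,
                 write_gmt, write_matrix, write_survival)
from .ips import compute_ips
from .simulate import (CellQCSimConfig, CountSimConfig, PlantedDE, PlantedSetActivity,
                       simulate_cells_for_qc, simulate_counts, simulate_survival,
                       synthetic_ips_table)
from .survival import cox_univariate, kaplan_meier, logrank_test_table

logger = logging.getLogger(__name__)

STAGES = ("qc", "enrichment", "fpi", "ips", "de", "survival", "integration")

# fixed per-stage seed offsets (stage-level reproducibility under toggling)
_SEED_OFFSETS = {"simulate": 11, "qc": 23, "survival": 47, "gsea": 59}
_SEED_MOD = 2 ** 31

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": list(STAGES),
    "tau": 0.25,
    "n_perm": 1000,
    "simulate": {
        "n_genes": 2000,
        "n_samples": 100,
        "n_de_group": 60,
        "n_de_stage": 60,
        "n_hub": 4,
        "de_log2fc": 3.0,
        "n_ferroptosis_extra": 30,
        "panel_boost": 4.0,
        "dispersion": 10.0,
    },
    "qc": {},
    "de": {"lfc_min": 1.0, "alpha": 0.05},
    "survival": {"beta": 0.5, "lambda0": 0.1, "censor_rate": 0.3},
}


def load_config(path: str | os.PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _stage_seed(seed: int, stage: str) -> int:
    return (int(seed) + _SEED_OFFSETS.get(stage, 0)) % _SEED_MOD


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, index: bool = True,
               index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", index=index,
              index_label=index_label)


def _write_json(obj: Any, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def build_simulation(config: dict) -> tuple[CountSimConfig, dict]:
    """Translate the pipeline simulation block into a count-generator
    configuration with two crossed factors and planted hub genes."""
    sim = config["simulate"]
    seed = _stage_seed(config["seed"], "simulate")
    n_samples = int(sim["n_samples"])
    half = n_samples // 2
    group = ("tumor",) * half + ("normal",) * (n_samples - half)
    stage = tuple("early" if i % 2 == 0 else "late" for i in range(n_samples))

    panel = default_regulator_panel()
    ips_table = synthetic_ips_table(seed=_stage_seed(config["seed"], "simulate"))
    hub_genes = tuple(f"HUB{i}" for i in range(1, int(sim["n_hub"]) + 1))
    named = (tuple(sorted(panel.positive.genes)) + tuple(sorted(panel.negative.genes))
             + tuple(ips_table["gene"]) + hub_genes)

    count_config = CountSimConfig(
        n_genes=int(sim["n_genes"]), n_samples=n_samples,
        factors={"group": group, "stage": stage},
        named_genes=named, dispersion=float(sim["dispersion"]), seed=seed,
    )
    auto = [g for g in count_config.gene_ids if g not in named]
    n_g, n_s, n_extra = (int(sim["n_de_group"]), int(sim["n_de_stage"]),
                         int(sim["n_ferroptosis_extra"]))
    if n_g + n_s + n_extra > len(auto):
        raise ValueError("not enough genes for the requested planted structure")
    de_group_only = tuple(auto[:n_g])
    de_stage_only = tuple(auto[n_g:n_g + n_s])
    ferro_extra = tuple(auto[n_g + n_s:n_g + n_s + n_extra])
    ferroptosis_set = hub_genes + ferro_extra

    lfc = float(sim["de_log2fc"])
    count_config = CountSimConfig(
        n_genes=count_config.n_genes, n_samples=n_samples,
        factors={"group": group, "stage": stage}, named_genes=named,
        dispersion=float(sim["dispersion"]), seed=seed,
        de=(
            PlantedDE(genes=de_group_only + hub_genes, log2fc=lfc,
                      factor="group", group="tumor"),
            PlantedDE(genes=de_stage_only + hub_genes, log2fc=lfc,
                      factor="stage", group="late"),
        ),
        set_activity=(
            PlantedSetActivity(name="POSITIVE_ACTIVE",
                               genes=tuple(sorted(panel.positive.genes)),
                               effect_size=float(sim["panel_boost"]),
                               factor="group", group="tumor"),
        ),
    )
    meta = {
        "hub_genes": list(hub_genes),
        "ferroptosis_set": list(ferroptosis_set),
        "de_group_planted": list(de_group_only + hub_genes),
        "de_stage_planted": list(de_stage_only + hub_genes),
        "group": list(group),
        "stage": list(stage),
        "ips_table": ips_table,
        "panel": panel,
    }
    return count_config, meta


def run_pipeline(config: dict, outdir: str | os.PathLike) -> dict:
    """Execute the configured stages in order and write a run manifest.

    Any stage error aborts the run; the partial manifest (with the failing
    stage named) is still written to ``outdir/manifest.json``.
    """
    config = merge_config(config)
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    seed = int(config["seed"])
    enabled = list(config["stages"])
    manifest: dict[str, Any] = {
        "seed": seed, "parameters": {k: v for k, v in config.items()},
        "stages": {}, "outputs": {},
    }

    def emit(name: str, writer) -> None:
        path = os.path.join(outdir, name)
        writer(path)
        manifest["outputs"][name] = _sha256(path)

    current = "simulate"
    try:
        t0 = _time.monotonic()
        count_config, meta = build_simulation(config)
        matrix, truth = simulate_counts(count_config)
        emit("counts.tsv", lambda p: write_matrix(matrix, p))
        ferro_set = GeneSet("FERROPTOSIS", frozenset(meta["ferroptosis_set"]),
                            "planted ferroptosis pathway set")
        panel = meta["panel"]
        emit("gene_sets.gmt", lambda p: write_gmt(
            GeneSetCollection([ferro_set, panel.positive, panel.negative]), p))
        groups = pd.Series(meta["group"], index=matrix.sample_ids)
        stage_factor = pd.Series(meta["stage"], index=matrix.sample_ids)
        manifest["stages"]["simulate"] = {
            "status": "ok", "n_genes": matrix.shape[0],
            "n_samples": matrix.shape[1],
            "seconds": round(_time.monotonic() - t0, 3),
        }

        normed = de_mod.normalize_counts(matrix)

        if "qc" in enabled:
            current = "qc"
            t0 = _time.monotonic()
            qc_config = CellQCSimConfig(seed=_stage_seed(seed, "qc"),
                                        **config.get("qc_simulate", {}))
            cell_matrix, cell_truth = simulate_cells_for_qc(qc_config)
            filtered, report = qc_mod.apply_cell_qc(
                cell_matrix, qc_mod.QCThresholds(**config.get("qc", {})))
            emit("qc_cells.tsv", lambda p: write_matrix(cell_matrix, p))
            emit("qc_report.json", lambda p: _write_json(report.to_dict(), p))
            emit("qc_truth.json", lambda p: cell_truth.to_json(p))
            manifest["stages"]["qc"] = {
                "status": "ok", "n_cells_in": report.n_cells_in,
                "n_cells_out": report.n_cells_out,
                "seconds": round(_time.monotonic() - t0, 3),
            }
        else:
            manifest["stages"]["qc"] = {"status": "skipped"}

        scores_frame = pd.DataFrame(index=matrix.sample_ids)
        if "enrichment" in enabled:
            current = "enrichment"
            t0 = _time.monotonic()
            es = ssgsea(normed, GeneSetCollection([ferro_set, panel.positive,
                                                   panel.negative]),
                        tau=float(config["tau"]))
            emit("enrichment_scores.tsv",
                 lambda p: _write_tsv(es.scores, p, index_label="set"))
            scores_frame["FERROPTOSIS"] = es.scores.loc["FERROPTOSIS"]
            manifest["stages"]["enrichment"] = {
                "status": "ok", "n_sets": es.scores.shape[0],
                "seconds": round(_time.monotonic() - t0, 3),
            }
        else:
            manifest["stages"]["enrichment"] = {"status": "skipped"}

        fpi_result = None
        if "fpi" in enabled:
            current = "fpi"
            t0 = _time.monotonic()
            fpi_result = compute_fpi(normed, panel, tau=float(config["tau"]),
                                     groups=groups)
            comparison = compare_fpi_groups(fpi_result, groups)
            strata = split_high_low(fpi_result.fpi, method="median")
            fpi_result.table["stratum"] = strata
            emit("fpi.tsv", lambda p: _write_tsv(fpi_result.table, p))
            emit("fpi_group_test.json", lambda p: _write_json(comparison, p))
            scores_frame["FPI"] = fpi_result.fpi
            manifest["stages"]["fpi"] = {
                "status": "ok", "n_samples": len(fpi_result.table),
                "group_p": comparison["pval"],
                "seconds": round(_time.monotonic() - t0, 3),
            }
        else:
            manifest["stages"]["fpi"] = {"status": "skipped"}

        if "ips" in enabled:
            current = "ips"
            t0 = _time.monotonic()
            ips_result = compute_ips(normed, meta["ips_table"])
            emit("ips.tsv", lambda p: _write_tsv(ips_result.table, p))
            for col in ("MHC", "CP", "EC", "SC", "AZ"):
                scores_frame[col] = ips_result.table[col]
            manifest["stages"]["ips"] = {
                "status": "ok", "n_samples": len(ips_result.table),
                "seconds": round(_time.monotonic() - t0, 3),
            }
        else:
            manifest["stages"]["ips"] = {"status": "skipped"}

        de_results = {}
        if "de" in enabled:
            current = "de"
            t0 = _time.monotonic()
            de_cfg = config["de"]
            for factor_name, labels in (("group", groups), ("stage", stage_factor)):
                result = de_mod.differential_expression(
                    matrix, labels, lfc_min=float(de_cfg["lfc_min"]),
                    alpha=float(de_cfg["alpha"]))
                de_results[factor_name] = result
                emit(f"de_{factor_name}.tsv",
                     lambda p, r=result: _write_tsv(r.table, p))
            # pre-ranked GSEA of the tumor/normal contrast against the
            # planted ferroptosis set
            ranking = de_results["group"].table["log2fc"]
            gsea = preranked_gsea(ranking, [ferro_set],
                                  n_perm=int(config["n_perm"]),
                                  seed=_stage_seed(seed, "gsea"))
            emit("gsea_group.tsv", lambda p: _write_tsv(gsea, p))
            manifest["stages"]["de"] = {
                "status": "ok",
                "n_significant_group": len(de_results["group"].significant_genes),
                "n_significant_stage": len(de_results["stage"].significant_genes),
                "seconds": round(_time.monotonic() - t0, 3),
            }
        else:
            manifest["stages"]["de"] = {"status": "skipped"}

        if "survival" in enabled and fpi_result is not None:
            current = "survival"
            t0 = _time.monotonic()
            surv_cfg = config["survival"]
            # standardize FPI so beta is a per-SD log hazard ratio
            fpi_z = (fpi_result.fpi - fpi_result.fpi.mean()) / fpi_result.fpi.std(ddof=0)
            table, _ = simulate_survival(
                fpi_z, beta=float(surv_cfg["beta"]),
                lambda0=float(surv_cfg["lambda0"]),
                censor_rate=float(surv_cfg["censor_rate"]),
                seed=_stage_seed(seed, "survival"))
            emit("survival.tsv", lambda p: write_survival(table, p))
            strata = fpi_result.table["stratum"]
            chi2, logrank_p = logrank_test_table(table, strata)
            km_rows = []
            for label in ("low", "high"):
                sub = table.data[strata.reindex(table.data["sample"]).to_numpy() == label]
                curve = kaplan_meier(sub["time"].to_numpy(), sub["event"].to_numpy())
                for t, n_at, d, s in zip(curve.times, curve.at_risk,
                                         curve.events, curve.survival):
                    km_rows.append({"stratum": label, "time": t, "at_risk": n_at,
                                    "events": d, "survival": s})
            emit("km_curves.tsv",
                 lambda p: _write_tsv(pd.DataFrame(km_rows), p, index=False))
            cox_unit = cox_univariate(table, covariate="score")
            cox_stratum = cox_univariate(
                table, covariate=(strata.reindex(table.data["sample"]) == "high")
                .to_numpy(dtype=float))
            emit("survival_stats.json", lambda p: _write_json({
                "logrank_chi2": chi2, "logrank_p": logrank_p,
                "cox_per_unit_fpi": vars(cox_unit),
                "cox_high_vs_low": vars(cox_stratum),
            }, p))
            manifest["stages"]["survival"] = {
                "status": "ok", "n": len(table), "logrank_p": logrank_p,
                "seconds": round(_time.monotonic() - t0, 3),
            }
        else:
            manifest["stages"]["survival"] = {
                "status": "skipped" if "survival" not in enabled
                else "skipped (requires fpi stage)"}

        if "integration" in enabled:
            current = "integration"
            t0 = _time.monotonic()
            if scores_frame.shape[1] >= 2:
                corr = spearman_matrix(scores_frame)
                emit("correlation_rho.tsv", lambda p: _write_tsv(corr.rho, p))
                emit("correlation_p.tsv", lambda p: _write_tsv(corr.pval, p))
                emit("correlation_dendrogram.nwk",
                     lambda p: open(p, "w", encoding="utf-8").write(corr.newick() + "\n"))
            hub_entry: dict[str, Any] = {"status": "ok"}
            if de_results:
                hub, counts = hub_gene_intersection(
                    de_results["group"].significant_genes,
                    de_results["stage"].significant_genes,
                    meta["ferroptosis_set"])
                emit("hub_genes.txt", lambda p: open(p, "w", encoding="utf-8")
                     .write("\n".join(hub) + "\n"))
                emit("hub_overlap.json", lambda p: _write_json(counts, p))
                hub_entry["n_hub_genes"] = len(hub)
                hub_entry["planted_hub_recovered"] = sorted(hub) == sorted(meta["hub_genes"])
            hub_entry["seconds"] = round(_time.monotonic() - t0, 3)
            manifest["stages"]["integration"] = hub_entry
        else:
            manifest["stages"]["integration"] = {"status": "skipped"}

        manifest["planted"] = {
            "hub_genes": meta["hub_genes"],
            "de_group": meta["de_group_planted"],
            "de_stage": meta["de_stage_planted"],
        }
    except Exception as exc:
        manifest["stages"][current] = {"status": "error", "message": str(exc)}
        _write_json(manifest, os.path.join(outdir, "manifest.json"))
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    _write_json(manifest, os.path.join(outdir, "manifest.json"))
    return manifest
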