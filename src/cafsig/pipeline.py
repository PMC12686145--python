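"""End-to-end orchestration: simulate → search → score → spatial → evaluate.

A run is described by a plain configuration mapping (usually loaded from
YAML).  All randomness derives from the single ``seed`` entry; rerunning
the same configuration reproduces byte-identical artifacts.

Artifacts written to the run directory:

* ``leaderboard.csv`` — every non-omitted combination with per-group AUCs.
* ``selected_genes.json`` — model genes of the winning combination.
* ``risk_scores.csv`` — per-sample risk score of the winning model.
* ``signature.gmt`` / ``caf_scores.csv`` — the up/down signature partition
  of the model genes and the resulting Caf.Sig scores per sample.
* ``meta_or.csv`` — per-model-gene odds-ratio meta-analysis (BH-adjusted).
* ``kdistance.csv``, ``rank_matrix.csv``, ``rra.csv``,
  ``group_comparison.json`` — the spatial proximity stage, with RRA run
  separately within responder and non-responder sections.
* ``evaluation.json``, ``calibration.csv``, ``dca.csv`` — the evaluation
  battery on the pooled external cohorts.
* ``manifest.json`` — config hash, seed, package version, artifact list.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .algorithms import reduced_manifest
from .evaluate import (
    calibration_table,
    confusion_at_threshold,
    net_benefit_curve,
    roc_auc,
    youden_threshold,
)
from .io import load_config, read_cohort, read_spatial_table, write_gmt, write_json
from .modelsearch import CohortGroupSplit, gene_or_meta, risk_score, run_search, standardize_cohorts
from .scoring import caf_sig_score, partition_signature
from .spatialprox import build_kdistance_table, compare_groups, rank_matrix, rra_aggregate
from .synthdata import (
    CohortSimSpec,
    SpatialSimSpec,
    TargetTypeSpec,
    simulate_cohorts,
    simulate_sections,
)

logger = logging.getLogger(__name__)

__all__ = ["demo_config", "run_pipeline"]


def demo_config() -> dict:
    """A small fully synthetic configuration that runs in well under a
    minute and exercises every stage."""
    return {
        "seed": 1,
        "synthetic": {
            "cohorts": {
                "n_cohorts": 5,
                "samples_per_cohort": 40,
                "n_genes": 120,
                "n_up": 12,
                "n_down": 12,
                "effect_size": 1.5,
            },
            "spatial": {
                "n_sections_responder": 3,
                "n_sections_nonresponder": 3,
                "n_reference_cells": 10,
                "cells_per_type": 60,
            },
        },
        "split": {
            "training": ["C01", "C02"],
            "internal": ["C03"],
            "external": ["C04", "C05"],
        },
        "manifest": "reduced-mini",
        "min_genes": 5,
        "top_k": 20,
        "k": 10,
        "alpha": 0.25,
        "meta_or_max_genes": 15,
    }


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _load_inputs(config: dict, seed: int):
    if "synthetic" in config:
        syn = config["synthetic"]
        cohorts, truth = simulate_cohorts(
            CohortSimSpec(**{**syn.get("cohorts", {}), "seed": seed})
        )
        sp = dict(syn.get("spatial", {}))
        if "target_types" in sp:
            sp["target_types"] = [TargetTypeSpec(**t) for t in sp["target_types"]]
        spatial, sp_truth = simulate_sections(SpatialSimSpec(**{**sp, "seed": seed + 1}))
        return cohorts, spatial, {"cohorts": truth, "spatial": sp_truth}
    cohorts = {}
    for entry in config["cohort_files"]:
        for key in ("expression", "labels"):
            if not Path(entry[key]).exists():
                raise FileNotFoundError(f"cohort {entry['name']}: missing {entry[key]}")
        cohorts[entry["name"]] = read_cohort(
            entry["name"], entry["expression"], entry["labels"]
        )
    spatial = None
    if config.get("spatial_file"):
        spatial = read_spatial_table(config["spatial_file"])
    return cohorts, spatial, None


def _resolve_manifest(config: dict):
    name = config.get("manifest", "default")
    if name == "default":
        return None
    if name == "reduced":
        return reduced_manifest()
    if name == "reduced-mini":  # six fast combos for smoke-scale runs
        keep = {"lasso+lasso", "lasso+ridge", "lasso+lda", "lasso+rf",
                "enet+naive_bayes", "enet+glmboost"}
        return [c for c in reduced_manifest() if c.combo_id in keep]
    raise ValueError(f"unknown manifest {name!r} (use default/reduced/reduced-mini)")


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the full pipeline for a configuration; return the run dir."""
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "cafsig_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def save_csv(df: pd.DataFrame, name: str, **kw) -> None:
        df.to_csv(outdir / name, index=False, **kw)
        artifacts.append(name)

    logger.info("stage: inputs")
    cohorts, spatial, truth = _load_inputs(config, seed)
    split = CohortGroupSplit(**config["split"])

    logger.info("stage: model search")
    leaderboard, fitted = run_search(
        cohorts,
        split,
        manifest=_resolve_manifest(config),
        min_genes=int(config.get("min_genes", 5)),
        top_k=int(config.get("top_k", 20)),
        seed=seed,
    )
    lb = leaderboard.table.copy()
    for col in ("auc_training", "auc_internal", "auc_external", "mean_auc"):
        lb[col] = lb[col].map(lambda v: f"{v:.6f}")
    save_csv(lb, "leaderboard.csv")
    top = leaderboard.top
    write_json(
        {"combo_id": top.combo_id, "selected_genes": top.selected_genes},
        outdir / "selected_genes.json",
    )
    artifacts.append("selected_genes.json")

    std, _genes = standardize_cohorts({k: cohorts[k] for k in split.all_cohorts})
    scores = pd.concat(
        [risk_score(top, std[c]).rename_axis("sample_id").rename(c) for c in split.all_cohorts],
        axis=0,
    )
    risk_df = pd.DataFrame(
        {
            "sample_id": scores.index,
            "cohort": np.repeat(split.all_cohorts, [std[c].shape[0] for c in split.all_cohorts]),
            "risk_score": [f"{v:.6f}" for v in scores.to_numpy()],
        }
    )
    save_csv(risk_df, "risk_scores.csv")

    logger.info("stage: signature scoring")
    train_expr = pd.concat([cohorts[c].expr for c in split.training], axis=1)
    train_labels = pd.concat([cohorts[c].labels for c in split.training])
    signature = partition_signature(train_expr, train_labels, top.selected_genes)
    write_gmt([signature.up, signature.down], outdir / "signature.gmt")
    artifacts.append("signature.gmt")
    caf_rows = []
    for c in split.all_cohorts:
        s = caf_sig_score(
            cohorts[c].expr, signature,
            scorer=config.get("scorer", "ssgsea"),
            alpha=float(config.get("alpha", 0.25)),
        )
        for sample, val in s.items():
            caf_rows.append((sample, c, f"{val:.6f}"))
    save_csv(pd.DataFrame(caf_rows, columns=["sample_id", "cohort", "caf_sig_score"]),
             "caf_scores.csv")

    logger.info("stage: odds-ratio meta-analysis")
    meta_genes = top.selected_genes[: int(config.get("meta_or_max_genes", 50))]
    meta_rows = []
    for g in meta_genes:
        try:
            row = gene_or_meta(g, cohorts, method=config.get("meta_method", "fixed"))
        except ValueError as exc:
            logger.warning("meta-analysis skipped for %s: %s", g, exc)
            continue
        lo, hi = row.ci
        meta_rows.append(
            {"gene": g, "odds_ratio": row.pooled_or, "ci_low": lo, "ci_high": hi,
             "p_value": row.p_value, "method": row.method}
        )
    meta = pd.DataFrame(meta_rows)
    if not meta.empty:
        from statsmodels.stats.multitest import multipletests

        meta["p_adjusted"] = multipletests(meta["p_value"], method="fdr_bh")[1]
        for col in ("odds_ratio", "ci_low", "ci_high", "p_value", "p_adjusted"):
            meta[col] = meta[col].map(lambda v: f"{v:.6g}")
    save_csv(meta, "meta_or.csv")

    if spatial is not None:
        logger.info("stage: spatial proximity")
        ref = config.get("reference_type", "iCAF")
        ktable = build_kdistance_table(spatial, ref, k=int(config.get("k", 10)))
        out_k = ktable.copy()
        out_k["k_distance"] = out_k["k_distance"].map(lambda v: f"{v:.6f}")
        save_csv(out_k, "kdistance.csv")
        rra_frames = []
        rank_frames = []
        for group in ("R", "NR"):
            sub = ktable[ktable["group"] == group]
            if sub.empty:
                continue
            rm = rank_matrix(sub)
            rm_out = rm.copy()
            rm_out.insert(0, "section_id", rm_out.index)
            rm_out.insert(0, "group", group)
            rank_frames.append(rm_out)
            rra = rra_aggregate(rm)
            rra.insert(0, "group", group)
            rra_frames.append(rra)
        save_csv(pd.concat(rank_frames, ignore_index=True), "rank_matrix.csv")
        rra_all = pd.concat(rra_frames, ignore_index=True)
        for col in ("rho", "rho_corrected"):
            rra_all[col] = rra_all[col].map(lambda v: f"{v:.6g}")
        save_csv(rra_all, "rra.csv")
        comparisons = {
            tt: compare_groups(ktable, tt)
            for tt in sorted(ktable["target_type"].unique())
        }
        write_json(comparisons, outdir / "group_comparison.json")
        artifacts.append("group_comparison.json")

    logger.info("stage: evaluation")
    ext_y = np.concatenate([cohorts[c].y for c in split.external])
    ext_prob = np.concatenate(
        [top.model.probability(std[c][top.feature_space].to_numpy()) for c in split.external]
    )
    curve = roc_auc(ext_prob, ext_y)
    thr = youden_threshold(ext_prob, ext_y)
    cm = confusion_at_threshold(ext_prob, ext_y, thr)
    write_json(
        {
            "external_auc": round(curve.auc, 6),
            "youden_threshold": round(thr, 6),
            "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
            "accuracy": round(cm.accuracy, 6),
            "sensitivity": round(cm.sensitivity, 6),
            "specificity": round(cm.specificity, 6),
        },
        outdir / "evaluation.json",
    )
    artifacts.append("evaluation.json")
    cal = calibration_table(ext_prob, ext_y)
    save_csv(cal.round(6), "calibration.csv")
    dca = net_benefit_curve(ext_prob, ext_y)
    save_csv(dca.round(6), "dca.csv")

    write_json(
        {
            "config_hash": _config_hash(config),
            "seed": seed,
            "version": __version__,
            "artifacts": sorted(set(artifacts)),
        },
        outdir / "manifest.json",
    )
    logger.info("run complete: %s", outdir)
    return outdir
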