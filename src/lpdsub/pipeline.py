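"""End-to-end orchestration: simulate/ingest -> preprocess -> select (K,
sigma) -> restart ensemble -> representative run -> clinical statistics ->
differential expression with run-support robustness -> baseline clustering
comparison.

Every stage writes plain TSV/JSON so the pieces remain independently
runnable, and a manifest records each stage's inputs, outputs and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lpdsub import data_io
from lpdsub.baseline import hclust_ward, kmeans_cluster, silhouette_scan, survival_by_cluster
from lpdsub.clinical import clinical_association_table
from lpdsub.de import pairwise_de, run_support_filter, size_factors_median_ratios
from lpdsub.ensemble import (
    count_poor_prognosis_runs,
    run_ensemble,
    select_representative_run,
)
from lpdsub.lpd import LPDHyperParams
from lpdsub.selection import grid_search, select_operating_point
from lpdsub.synthetic import simulate_cohort

log = logging.getLogger(__name__)

DEFAULTS = {
    "n_features": 500,
    "k_values": [2, 3, 4, 5, 6],
    "sigma_values": [-0.1, -0.01, -0.001],
    "folds": 5,
    "restarts": 3,
    "n_runs": 100,
    "base_seed": 1,
    "alpha": 0.05,
    "lfc": 1.5,
    "padj": 0.01,
    "support": 0.8,
    "baseline_k_range": [2, 3, 4, 5, 6],
    "max_iter": 200,
    "outdir": "lpdsub_out",
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict | None) -> dict:
    """Fill defaults and enumerate contradictions; idempotent."""
    cfg = dict(DEFAULTS)
    cfg.update(config or {})
    errors = []
    for frac_key in ("alpha", "padj", "support"):
        v = cfg[frac_key]
        if not (0 <= v <= 1):
            errors.append(f"{frac_key}={v} outside [0, 1]")
    if cfg["lfc"] <= 0:
        errors.append("lfc must be positive")
    if cfg["n_features"] < 1:
        errors.append("n_features must be >= 1")
    if cfg["folds"] < 2:
        errors.append("folds must be >= 2")
    if cfg["n_runs"] < 1:
        errors.append("n_runs must be >= 1")
    if "simulate" not in cfg and "counts" not in cfg and "expression" not in cfg:
        errors.append("config needs a 'simulate' block or 'counts'/'expression' paths")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Execute the full study; returns a result bundle and writes artifacts.

    Stages and seeds are recorded in ``manifest.json`` under the output
    directory; reruns with the same config and seed are bit-identical for
    the deterministic stages.
    """
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    results: dict = {"config": cfg}

    def record(stage: str, seeds=None, **files):
        entry = {"stage": stage, "seeds": seeds}
        entry["files"] = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in files.items()
        }
        manifest.append(entry)

    # --- stage 1: data ---------------------------------------------------
    base_seed = int(cfg["base_seed"])
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", base_seed)
        cohort = simulate_cohort(**sim)
        counts, clinical = cohort["counts"], cohort["clinical"]
        expr_full = cohort["expression"]
        sf = size_factors_median_ratios(counts)
        counts_path = outdir / "counts.tsv"
        clin_path = outdir / "clinical.tsv"
        data_io.write_count_matrix(counts, counts_path)
        data_io.write_clinical_table(clinical, clin_path)
        record("simulate", seeds=[sim["seed"]], counts=counts_path, clinical=clin_path)
    else:
        counts = data_io.read_count_matrix(cfg["counts"]) if "counts" in cfg else None
        clinical = (
            data_io.read_clinical_table(cfg["clinical"]) if "clinical" in cfg else None
        )
        if counts is not None:
            sf = size_factors_median_ratios(counts)
            expr_full = data_io.log_normalize(counts, sf)
        else:
            expr_full = data_io.read_expression_matrix(cfg["expression"])
            sf = None
        record("ingest")

    n_feat = min(cfg["n_features"], len(expr_full.gene_ids))
    expr = data_io.select_top_variance(expr_full, n_feat)
    expr_path = outdir / "expression_topvar.tsv"
    data_io.write_expression_matrix(expr, expr_path)
    record("feature_selection", expression=expr_path)
    results["expression"] = expr

    # --- stage 2: hyperparameter selection -------------------------------
    grid = grid_search(
        expr,
        K_values=cfg["k_values"],
        sigma_values=cfg["sigma_values"],
        folds=cfg["folds"],
        restarts=cfg["restarts"],
        seed=base_seed,
        max_iter=cfg["max_iter"],
    )
    K_sel, sigma_sel = select_operating_point(grid)
    grid_path = outdir / "selection_grid.json"
    grid_path.write_text(json.dumps(
        {**grid.to_dict(), "selected": {"K": K_sel, "sigma": sigma_sel}}, indent=2))
    record("model_selection", seeds=[base_seed], grid=grid_path)
    results["selection"] = {"K": K_sel, "sigma": sigma_sel, "grid": grid}
    log.info("selected K=%d sigma=%g", K_sel, sigma_sel)

    # --- stage 3: ensemble + representative run --------------------------
    hp = LPDHyperParams(K=K_sel, sigma_spread=sigma_sel, max_iter=cfg["max_iter"])
    ens = run_ensemble(expr, hp, cfg["n_runs"], base_seed, clinical)
    summary = pd.DataFrame(
        [
            {"seed": r.seed, "logrank_p": r.logrank_p,
             "worst_process": r.worst_process, "worst_unique": r.worst_unique,
             "error": r.error}
            for r in ens.runs
        ]
    )
    ens_path = outdir / "ensemble_summary.tsv"
    summary.to_csv(ens_path, sep="\t", index=False)
    n_poor = count_poor_prognosis_runs(ens, cfg["alpha"]) if clinical is not None else 0
    results["ensemble"] = ens
    results["n_poor_prognosis_runs"] = n_poor
    record("ensemble", seeds=list(range(base_seed, base_seed + cfg["n_runs"])),
           summary=ens_path)

    rep_idx = select_representative_run(ens, cfg["alpha"]) if n_poor else None
    if rep_idx is None:
        log.warning("no qualifying runs; falling back to the best-bound run")
        bounds = [r.fit.bound_trace[-1] if r.fit else -np.inf for r in ens.runs]
        rep_idx = int(np.argmax(bounds))
    rep = ens.runs[rep_idx]
    results["representative_run"] = rep
    assign_path = outdir / "assignments.tsv"
    pd.DataFrame({
        "sample_id": rep.assignment.sample_ids,
        "process": rep.assignment.labels,
        "membership": rep.assignment.weights,
    }).to_csv(assign_path, sep="\t", index=False)
    record("representative_run", seeds=[rep.seed], assignments=assign_path)

    # --- stage 4: clinical statistics ------------------------------------
    if clinical is not None:
        assoc = clinical_association_table(rep.assignment.labels, clinical.table)
        assoc_path = outdir / "clinical_associations.tsv"
        assoc.to_csv(assoc_path, sep="\t", index=False)
        results["clinical_associations"] = assoc
        record("clinical_stats", associations=assoc_path)

    # --- stage 5: differential expression with run support ---------------
    if counts is not None:
        rep_calls = pairwise_de(
            counts, rep.assignment.labels, sf,
            lfc_threshold=cfg["lfc"], padj_threshold=cfg["padj"],
        )
        worst = rep.worst_process
        per_run_sets = []
        for r in ens.qualifying(cfg["alpha"]):
            calls = pairwise_de(
                counts, r.assignment.labels, sf,
                lfc_threshold=cfg["lfc"], padj_threshold=cfg["padj"],
            )
            per_run_sets.append(calls.get(r.worst_process, set()))
        if per_run_sets:
            robust = run_support_filter(per_run_sets, cfg["support"])
        else:
            robust = pd.DataFrame(columns=["transcript", "direction", "run_support"])
        de_path = outdir / "de_robust.tsv"
        robust.to_csv(de_path, sep="\t", index=False)
        results["de_robust"] = robust
        results["de_representative"] = rep_calls.get(worst, set()) if worst is not None else set()
        record("differential_expression", de=de_path)

    # --- stage 6: baseline comparison ------------------------------------
    scan = silhouette_scan(expr, cfg["baseline_k_range"], seed=base_seed)
    baseline_rows = []
    for method, best_k in scan["best_k"].items():
        if method == "kmeans":
            labels = kmeans_cluster(expr, best_k, seed=base_seed).labels
        else:
            labels = hclust_ward(expr, best_k).labels
        row = {"method": method, "k": best_k,
               "silhouette": scan["scores"][method][best_k]}
        if clinical is not None:
            row["logrank_p"] = survival_by_cluster(labels, expr.sample_ids, clinical)
        baseline_rows.append(row)
    baseline = pd.DataFrame(baseline_rows)
    base_path = outdir / "baseline_comparison.tsv"
    baseline.to_csv(base_path, sep="\t", index=False)
    results["baseline"] = baseline
    record("baseline_clustering", seeds=[base_seed], comparison=base_path)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))
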