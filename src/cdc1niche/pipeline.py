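"""Run configuration and the stage orchestrator.

A run is described by a flat key-value config (YAML). Unknown keys are
rejected before any stage executes. Every run writes a manifest echoing the
resolved parameters, seed, input checksums and per-stage row counts, so any
reported number is regenerable from config + seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, mif, signatures
from . import hubs as hubs_mod
from . import synthetic
from .types import EXCLUDED, GeneSignature

logger = logging.getLogger("cdc1niche")

STAGES = ("simulate-bulk", "simulate-tissue", "simulate-st",
          "signatures", "mif", "hubs")

#: allowed config keys per stage (beyond the globals)
_GLOBAL_KEYS = {"stage", "outdir", "seed", "log_level"}
_STAGE_KEYS: dict[str, set[str]] = {
    "simulate-bulk": {"n_samples", "n_genes", "latent_corr", "response_effect",
                      "nb_dispersion", "baseline_mean"},
    "simulate-tissue": {"field_width", "field_height", "n_cdc1", "n_cd8",
                        "n_cd4", "n_other", "attraction_fraction",
                        "displacement_sd"},
    "simulate-st": {"n_cells", "field_width", "field_height", "marker_fold",
                    "activation_fold", "count_depth", "n_background_genes"},
    "signatures": {"counts", "clinical", "gene_sets", "candidates",
                   "min_count", "min_frac", "rho_min", "alpha"},
    "mif": {"cells", "margin_um", "bin_um", "min_cells", "clinical"},
    "hubs": {"counts_prefix", "gene_sets", "radius_um", "min_molecules",
             "n_perm", "resolution", "knn_k"},
}


@dataclass
class RunConfig:
    """Validated flat configuration for one pipeline stage."""

    stage: str
    outdir: Path
    seed: int = 0
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "stage" not in raw:
            raise ValueError("config missing 'stage'")
        stage = raw["stage"]
        if stage not in STAGES:
            raise ValueError(f"unknown stage: {stage}")
        allowed = _GLOBAL_KEYS | _STAGE_KEYS[stage]
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ValueError("config missing 'outdir'")
        params = {k: v for k, v in raw.items() if k not in _GLOBAL_KEYS}
        return cls(stage=stage, outdir=Path(raw["outdir"]),
                   seed=int(raw.get("seed", 0)),
                   log_level=str(raw.get("log_level", "INFO")), params=params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        return cls.from_dict(raw)


def _paths(value) -> list[Path]:
    if isinstance(value, (list, tuple)):
        return [Path(v) for v in value]
    return [Path(v) for v in str(value).split(",") if v]


def run_pipeline(config: RunConfig) -> dict:
    """Execute one stage and return its manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    config.outdir.mkdir(parents=True, exist_ok=True)
    stage_fn = {
        "simulate-bulk": _run_simulate_bulk,
        "simulate-tissue": _run_simulate_tissue,
        "simulate-st": _run_simulate_st,
        "signatures": _run_signatures,
        "mif": _run_mif,
        "hubs": _run_hubs,
    }[config.stage]
    manifest: dict = {
        "tool_version": __version__,
        "stage": config.stage,
        "seed": config.seed,
        "params": {k: str(v) for k, v in sorted(config.params.items())},
        "config_hash": io.config_hash(
            {"stage": config.stage, "seed": config.seed, **config.params}),
        "inputs": {},
        "counts": {},
        "outputs": [],
    }
    try:
        stage_fn(config, manifest)
    except Exception as exc:
        raise RuntimeError(f"stage {config.stage!r} failed: {exc}") from exc
    (config.outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest


def _record_input(manifest: dict, path: Path) -> None:
    manifest["inputs"][str(path)] = io.file_checksum(path)


def _record_output(manifest: dict, path: Path) -> None:
    manifest["outputs"].append(str(path))


# ---------------------------------------------------------------------------
# simulation stages
# ---------------------------------------------------------------------------

def _run_simulate_bulk(config: RunConfig, manifest: dict) -> None:
    p = config.params
    params = synthetic.BulkSimParams(seed=config.seed, **{
        k: type(getattr(synthetic.BulkSimParams(), k))(v)
        for k, v in p.items()})
    cm, clin, truth = synthetic.gen_bulk_cohort(params)
    io.write_expression_tsv(cm, config.outdir / "counts.tsv.gz")
    io.write_clinical(clin, config.outdir / "clinical.csv")
    truth.latents.to_csv(config.outdir / "true_latents.csv")
    io.write_gmt(truth.signature_genes, config.outdir / "true_signatures.gmt")
    manifest["counts"] = {"genes": len(cm.genes), "samples": len(cm.samples)}
    for name in ("counts.tsv.gz", "clinical.csv", "true_latents.csv",
                 "true_signatures.gmt"):
        _record_output(manifest, config.outdir / name)


def _run_simulate_tissue(config: RunConfig, manifest: dict) -> None:
    params = synthetic.TissueSimParams(seed=config.seed, **{
        k: type(getattr(synthetic.TissueSimParams(), k))(v)
        for k, v in config.params.items()})
    table = synthetic.gen_tissue(params)
    io.write_cell_table(table, config.outdir / "cells.csv")
    manifest["counts"] = {"cells": len(table)}
    _record_output(manifest, config.outdir / "cells.csv")


def _run_simulate_st(config: RunConfig, manifest: dict) -> None:
    params = synthetic.STSimParams(seed=config.seed, **{
        k: type(getattr(synthetic.STSimParams(), k))(v)
        for k, v in config.params.items()})
    matrix = synthetic.gen_spatial_transcriptome(params)
    io.write_cell_transcript_matrix(matrix, config.outdir / "st")
    manifest["counts"] = {"cells": matrix.n_cells, "genes": len(matrix.genes)}
    _record_output(manifest, config.outdir / "st.mtx")


# ---------------------------------------------------------------------------
# analysis arms
# ---------------------------------------------------------------------------

def _run_signatures(config: RunConfig, manifest: dict) -> None:
    """Arm: normalize -> (optional derivation) -> score -> rescale ->
    group comparison and correlation panel."""
    p = config.params
    count_paths = _paths(p["counts"])
    cohorts = []
    for path in count_paths:
        _record_input(manifest, path)
        cohorts.append(io.read_expression(path))
    sigs: list[GeneSignature] = []
    if "gene_sets" in p:
        _record_input(manifest, Path(p["gene_sets"]))
        for name, genes in io.read_gmt(p["gene_sets"]).items():
            sigs.append(GeneSignature(name, genes,
                                      {g: "curated" for g in genes}))
    if "candidates" in p:
        _record_input(manifest, Path(p["candidates"]))
        pool = [g for gs in io.read_gmt(p["candidates"]).values() for g in gs]
        sigs.append(signatures.derive_signature(
            cohorts, pool,
            min_count=float(p.get("min_count", 5)),
            min_frac=float(p.get("min_frac", 0.5)),
            rho_min=float(p.get("rho_min", 0.4)),
            alpha=float(p.get("alpha", 0.05))))
    if not sigs:
        raise ValueError("signatures arm needs 'gene_sets' and/or 'candidates'")

    clinical = None
    if "clinical" in p:
        _record_input(manifest, Path(p["clinical"]))
        clinical = io.read_clinical(Path(p["clinical"]))

    all_scores, stats_report = [], {}
    for ci, (path, cm) in enumerate(zip(count_paths, cohorts)):
        cohort_name = path.stem.replace(".tsv", "")
        logger.info("cohort %s: %d genes x %d samples",
                    cohort_name, len(cm.genes), len(cm.samples))
        norm = signatures.log2_cpm(cm)
        table = signatures.score_table(norm, sigs)
        table.insert(0, "cohort", cohort_name)
        all_scores.append(table)
        cohort_stats: dict = {}
        raw_by_sig = {s.name: table.loc[table["signature"] == s.name,
                                        "raw_score"].to_numpy() for s in sigs}
        if clinical is not None:
            sub = clinical.table.set_index("sample_id").reindex(cm.samples)
            from .types import ClinicalTable
            aligned = ClinicalTable(sub.reset_index())
            cohort_stats["group_compare"] = {
                name: signatures.group_compare(raw, aligned).to_dict("records")
                for name, raw in raw_by_sig.items()}
        if len(sigs) > 1:
            pairs = {}
            names = list(raw_by_sig)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    pairs[f"{names[i]}~{names[j]}"] = (
                        raw_by_sig[names[i]], raw_by_sig[names[j]])
            cohort_stats["correlations"] = signatures.correlation_panel(
                pairs).to_dict("records")
        stats_report[cohort_name] = cohort_stats
        manifest["counts"][cohort_name] = {
            "genes": len(cm.genes), "samples": len(cm.samples)}
    scores = pd.concat(all_scores, ignore_index=True)
    scores.to_csv(config.outdir / "scores.csv", index=False)
    (config.outdir / "stats.json").write_text(
        json.dumps(stats_report, indent=2, default=str))
    _record_output(manifest, config.outdir / "scores.csv")
    _record_output(manifest, config.outdir / "stats.json")


def _run_mif(config: RunConfig, manifest: dict) -> None:
    """Arm: threshold -> phenotype -> trim -> area -> densities ->
    distances -> group tests (if clinical labels given)."""
    p = config.params
    margin = float(p.get("margin_um", 20.0))
    bin_um = float(p.get("bin_um", 50.0))
    min_cells = int(p.get("min_cells", 1))
    summaries, thresholds_out = [], {}
    for path in _paths(p["cells"]):
        _record_input(manifest, path)
        table = io.read_cell_table(path)
        sample = path.stem
        n_in = len(table)
        thr = mif.marker_thresholds(table)
        thresholds_out[sample] = thr
        table = mif.assign_phenotypes(table, thr)
        bounds = (table["x_um"].min(), table["y_um"].min(),
                  table["x_um"].max(), table["y_um"].max())
        table = mif.trim_border(table, bounds, margin)
        if len(table) < min_cells:
            logger.warning("sample %s below min_cells after trimming", sample)
            continue
        area = mif.estimate_tissue_area(table, bin_um)
        summary = mif.distance_summary(table, sample)
        summary.update({f"density_{k}": v
                        for k, v in mif.densities(table, area).items()})
        summary["area_mm2"] = area
        summaries.append(summary)
        manifest["counts"][sample] = {"cells_in": n_in, "cells_kept": len(table)}
        logger.info("sample %s: %d -> %d cells", sample, n_in, len(table))
    summary_df = pd.DataFrame(summaries)
    summary_df.to_csv(config.outdir / "distance_summary.csv", index=False)
    (config.outdir / "thresholds.json").write_text(
        json.dumps(thresholds_out, indent=2))
    _record_output(manifest, config.outdir / "distance_summary.csv")
    _record_output(manifest, config.outdir / "thresholds.json")

    if "clinical" in p and len(summary_df):
        _record_input(manifest, Path(p["clinical"]))
        clin = io.read_clinical(Path(p["clinical"]))
        merged = summary_df.merge(clin.table, on="sample_id")
        benefit = merged["response"].isin(["CR", "PR", "good"])
        tests = {}
        for col in ("mean_min_cdc1_cd8", "mean_min_cdc1_cd4",
                    "mean_triad_radius"):
            vals = merged[col]
            ok = vals != EXCLUDED
            a = vals[ok & benefit].astype(float).to_numpy()
            b = vals[ok & ~benefit].astype(float).to_numpy()
            if len(a) and len(b):
                stat, pval = mif.group_distance_compare(a, b)
                tests[col] = {"statistic": stat, "p": pval,
                              "n_benefit": len(a), "n_no_benefit": len(b)}
        (config.outdir / "group_tests.json").write_text(
            json.dumps(tests, indent=2))
        _record_output(manifest, config.outdir / "group_tests.json")


def _run_hubs(config: RunConfig, manifest: dict) -> None:
    """Arm: qc -> detect (threshold + cluster) -> consensus -> build ->
    classify -> DE -> preranked GSEA (if gene sets given)."""
    p = config.params
    prefix = Path(p["counts_prefix"])
    _record_input(manifest, prefix.with_suffix(".mtx"))
    matrix = io.read_cell_transcript_matrix(prefix)
    n_in = matrix.n_cells
    matrix = hubs_mod.qc_filter(matrix, int(p.get("min_molecules", 50)))
    logger.info("qc: %d -> %d cells", n_in, matrix.n_cells)
    thr_calls = hubs_mod.detect_threshold(matrix)
    clu_calls = hubs_mod.detect_cluster(
        matrix, resolution=float(p.get("resolution", 2.0)),
        k=int(p.get("knn_k", 15)), seed=config.seed)
    cons = hubs_mod.consensus(thr_calls, clu_calls)
    mask = (cons["consensus"] != "none").to_numpy()
    hub_set = hubs_mod.build_hubs(matrix, mask,
                                  radius_um=float(p.get("radius_um", 10.0)))
    hub_set = hubs_mod.classify_hubs(hub_set)
    hub_set.to_frame().to_csv(config.outdir / "hubs.csv", index=False)
    _record_output(manifest, config.outdir / "hubs.csv")
    manifest["counts"] = {
        "cells_in": n_in, "cells_qc": matrix.n_cells,
        "candidates": int(mask.sum()), "hubs": len(hub_set),
        "rich": sum(h.hub_class == "cDC1-rich" for h in hub_set),
    }
    de = hub_de_safe(hub_set)
    if de is not None:
        de.to_csv(config.outdir / "hub_de.csv", index=False)
        _record_output(manifest, config.outdir / "hub_de.csv")
        if "gene_sets" in p:
            _record_input(manifest, Path(p["gene_sets"]))
            sets = io.read_gmt(p["gene_sets"])
            ranked = pd.Series(de["log2fc"].to_numpy(), index=de["gene"])
            gsea = hubs_mod.preranked_gsea(
                ranked, sets, n_perm=int(p.get("n_perm", 1000)),
                seed=config.seed)
            gsea.to_csv(config.outdir / "gsea.csv", index=False)
            _record_output(manifest, config.outdir / "gsea.csv")


def hub_de_safe(hub_set) -> pd.DataFrame | None:
    """hub_de, degrading to None (with a log message) when one class is
    too small instead of aborting the whole arm."""
    try:
        return hubs_mod.hub_de(hub_set)
    except ValueError as exc:
        logger.warning("hub DE skipped: %s", exc)
        return None
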