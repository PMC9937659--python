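"""End-to-end orchestration of the analysis stages over a run directory.

Stage layout inside a run directory ``out``:

    out/data/        synthetic (or user-supplied) input files
    out/degs.tsv, deg_matrix.tsv
    out/enrichment_PROMOTE.tsv, enrichment_INHIBIT.tsv, cluster_assignments.tsv
    out/ora_results.tsv, pathway_matrix.tsv
    out/cv_report.tsv, cv_probabilities.tsv, threshold_curve.tsv,
        feature_importances.tsv, tree_both.txt, tree_both.dot
    out/predictions.tsv
    out/report.md, config.yaml, run.log

The single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence([seed, stage_index])`` (stage 0 = simulation,
stage 1 = models), so rerunning one stage alone reproduces its randomness.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from .config import (INHIBIT, PROMOTE, UNKNOWN, EnrichmentConfig, ModelConfig,
                     ORAConfig, PipelineConfig, save_pipeline_config)
from .enrichment import cluster_profiles, enrich_targets
from .expression import DEGProfiles, build_deg_feature_matrix, degs_from_dataset
from .io import read_activity_matrix, read_expression_dataset, read_labels, read_matrix, write_matrix
from .ora import read_gmt, run_ora
from .report import write_report
from .simulate import simulate_bundle, write_dataset

logger = logging.getLogger(__name__)

_STAGE_SIMULATION, _STAGE_MODEL = 0, 1


def stage_seed(seed: int, stage: int) -> int:
    """Derive a per-stage child seed (< 2**31) from the global seed."""
    return int(np.random.SeedSequence([int(seed), stage]).generate_state(1)[0] % (2 ** 31))


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input file missing: {path}")
    logger.info("input %s sha256=%s", path.name, file_checksum(path))
    return path


def run_simulate(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate the synthetic dataset into out/data (simulation seed derived
    from the global seed)."""
    sim_cfg = cfg.simulation
    sim_cfg = type(sim_cfg)(**{**sim_cfg.__dict__,
                               "seed": stage_seed(cfg.seed, _STAGE_SIMULATION)})
    data_dir = Path(out_dir) / "data"
    bundle = simulate_bundle(sim_cfg)
    manifest = write_dataset(bundle, data_dir)
    logger.info("simulated dataset with %d files into %s", len(manifest), data_dir.name)
    return data_dir


def run_degs(cfg: PipelineConfig, out_dir: str | Path,
             data_dir: str | Path | None = None) -> DEGProfiles:
    """Probe matrix → normalized, collapsed, averaged → DEG calls + matrix."""
    out = Path(out_dir)
    data = Path(data_dir) if data_dir else out / "data"
    for name in ("expression.tsv", "samples.tsv", "probe_map.tsv"):
        _require(data / name)
    dataset = read_expression_dataset(data)
    profiles = degs_from_dataset(dataset, cfg.degs)
    profiles.table.to_csv(out / "degs.tsv", sep="\t", index=False)
    write_matrix(build_deg_feature_matrix(profiles), out / "deg_matrix.tsv")
    logger.info("called %d DEG entries over %d compounds",
                len(profiles.table), len(profiles.compounds))
    return profiles


def run_enrich(cfg: PipelineConfig, out_dir: str | Path,
               data_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Per-phenotype target enrichment plus MoA clustering of the bioactivity
    profiles over the union of significantly enriched targets."""
    out = Path(out_dir)
    data = Path(data_dir) if data_dir else out / "data"
    study = read_activity_matrix(_require(data / "targets_study.tsv"),
                                 cfg.enrichment.activity_cutoff)
    background = read_activity_matrix(_require(data / "targets_background.tsv"),
                                      cfg.enrichment.activity_cutoff)
    labels = read_labels(_require(data / "labels.tsv"))
    results = {}
    enriched_targets: list[str] = []
    for phenotype in (PROMOTE, INHIBIT):
        res = enrich_targets(phenotype, study, labels, background, cfg.enrichment)
        res.to_csv(out / f"enrichment_{phenotype}.tsv", sep="\t", index=False)
        results[phenotype] = res
        enriched_targets += list(res.loc[res["significant"], "target_id"])
    enriched_targets = sorted(set(enriched_targets))
    labelled = labels[labels != UNKNOWN].index
    if len(enriched_targets) >= 2 and len(labelled) >= 2:
        profile = study.binarize().loc[labelled, enriched_targets]
        cr = cluster_profiles(profile, metric=cfg.enrichment.cluster_metric,
                              linkage=cfg.enrichment.cluster_linkage, k=4)
        cr.row_clusters.to_frame().to_csv(out / "cluster_assignments.tsv", sep="\t")
    else:
        logger.warning("too few enriched targets to cluster; skipping cluster output")
    logger.info("enrichment: %d significant targets across phenotypes",
                len(enriched_targets))
    return results


def _profiles_from_files(out: Path) -> DEGProfiles:
    table = pd.read_csv(_require(out / "degs.tsv"), sep="\t")
    matrix = read_matrix(_require(out / "deg_matrix.tsv"))
    return DEGProfiles(table=table, gene_universe=list(matrix.columns),
                       compounds=list(matrix.index))


def run_ora_stage(cfg: PipelineConfig, out_dir: str | Path,
                  data_dir: str | Path | None = None) -> pd.DataFrame:
    """Per-compound ORA against the GMT collection + recurrence matrix."""
    out = Path(out_dir)
    data = Path(data_dir) if data_dir else out / "data"
    profiles = _profiles_from_files(out)
    collection = read_gmt(_require(data / "genesets.gmt"),
                          universe=profiles.gene_universe)
    results, matrix = run_ora(profiles, collection, cfg.ora)
    results.to_csv(out / "ora_results.tsv", sep="\t", index=False)
    write_matrix(matrix, out / "pathway_matrix.tsv")
    logger.info("ORA: %d retained pathways", matrix.shape[0])
    return results


def _feature_blocks(out: Path, data: Path, cutoff: float):
    tp = read_activity_matrix(_require(data / "targets_study.tsv"), cutoff).binarize()
    deg = read_matrix(_require(out / "deg_matrix.tsv"))
    labels = read_labels(_require(data / "labels.tsv"))
    return tp, deg, labels


_MODEL_MODES = {"gene": "DEG_only", "tp": "TP_only", "both": "both"}


def run_train(cfg: PipelineConfig, out_dir: str | Path,
              data_dir: str | Path | None = None) -> dict[str, clf.CVReport]:
    """LOO CV of the gene-only, TP-only and fused forests on the labelled
    compounds; threshold curve, Gini importances and explainable tree export."""
    out = Path(out_dir)
    data = Path(data_dir) if data_dir else out / "data"
    tp, deg, labels = _feature_blocks(out, data, cfg.enrichment.activity_cutoff)
    labelled = labels[labels != UNKNOWN]
    mcfg = type(cfg.model)(**{**cfg.model.__dict__,
                              "seed": stage_seed(cfg.seed, _STAGE_MODEL)})
    reports: dict[str, clf.CVReport] = {}
    rows = []
    prob_cols = {}
    for key, mode in _MODEL_MODES.items():
        fm = clf.fuse_features(tp, deg, mode=mode)
        fused = fm.values.loc[fm.values.index.intersection(labelled.index)]
        rep = clf.loo_cv(fused, labelled, mcfg, model_kind="forest")
        reports[key] = rep
        prob_cols[f"p_promote_{key}"] = rep.probabilities
        rows.append({"model": key, **{k: v for k, v in rep.metrics.items()}})
    pd.DataFrame(rows).to_csv(out / "cv_report.tsv", sep="\t", index=False)
    probs = pd.DataFrame(prob_cols)
    probs["label"] = labelled.loc[probs.index]
    probs.index.name = "compound_id"
    probs.to_csv(out / "cv_probabilities.tsv", sep="\t")

    curve, _ = clf.calibrate_threshold(reports["both"].probabilities, labelled,
                                       configured=mcfg.promoter_threshold)
    curve.to_csv(out / "threshold_curve.tsv", sep="\t", index=False)

    fm_both = clf.fuse_features(tp, deg, mode="both")
    X_lab = fm_both.values.loc[fm_both.values.index.intersection(labelled.index)]
    forest = clf.train_forest(X_lab, labelled, mcfg)
    top = clf.gini_top_features(forest, list(X_lab.columns), k=mcfg.top_k_features)
    top.to_csv(out / "feature_importances.tsv", sep="\t", index=False)
    compact = clf.refit_top_features(X_lab, labelled, list(top["feature"]), mcfg)
    (out / "tree_both.txt").write_text(compact["tree_text"])
    (out / "tree_both.dot").write_text(compact["tree_dot"])
    logger.info("LOO CV done: AUC both=%.3f gene=%.3f tp=%.3f",
                reports["both"].metrics["roc_auc"],
                reports["gene"].metrics["roc_auc"],
                reports["tp"].metrics["roc_auc"])
    return reports


def run_predict(cfg: PipelineConfig, out_dir: str | Path,
                data_dir: str | Path | None = None) -> pd.DataFrame:
    """Fit the three final forests on all labelled compounds and rank the
    unknown compounds by promoter probability."""
    out = Path(out_dir)
    data = Path(data_dir) if data_dir else out / "data"
    tp, deg, labels = _feature_blocks(out, data, cfg.enrichment.activity_cutoff)
    labelled = labels[labels != UNKNOWN]
    unknown_ids = labels[labels == UNKNOWN].index
    mcfg = type(cfg.model)(**{**cfg.model.__dict__,
                              "seed": stage_seed(cfg.seed, _STAGE_MODEL)})
    models, blocks = {}, {}
    for key, mode in _MODEL_MODES.items():
        fm = clf.fuse_features(tp, deg, mode=mode)
        X_lab = fm.values.loc[fm.values.index.intersection(labelled.index)]
        model = clf.train_forest(X_lab, labelled, mcfg)
        models[key] = (model, list(fm.values.columns))
        unk = fm.values.index.intersection(unknown_ids)
        blocks[key] = fm.values.loc[unk]
    table = clf.predict_unknowns(models, blocks, threshold=mcfg.promoter_threshold)
    table.to_csv(out / "predictions.tsv", sep="\t")
    logger.info("ranked %d unknown compounds", len(table))
    return table


def run_all(cfg: PipelineConfig, out_dir: str | Path,
            data_dir: str | Path | None = None) -> Path:
    """Chain simulate → degs → enrich → ora → train → predict → report.

    When ``data_dir`` is given the simulation is skipped and the pipeline
    consumes the user-supplied files instead.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_pipeline_config(cfg, out / "config.yaml")
    logger.info("pipeline seed %d", cfg.seed)
    data = Path(data_dir) if data_dir else run_simulate(cfg, out)
    run_degs(cfg, out, data)
    run_enrich(cfg, out, data)
    run_ora_stage(cfg, out, data)
    run_train(cfg, out, data)
    run_predict(cfg, out, data)
    write_report(out)
    return out
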