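"""Planted-truth recovery benchmarks over the synthetic generator.

Each benchmark runs the real pipeline stages on seeded synthetic datasets
with known planted structure and measures how well the stage recovers it:
enriched-target ranking, DEG sensitivity/specificity, and leave-one-out
classifier performance (including a permuted-label null and Gini feature
recovery). Seeds are fanned out from one base seed via SeedSequence so a
whole benchmark is reproducible from a single integer.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import classifier as clf
from .config import INHIBIT, PROMOTE, UNKNOWN, ModelConfig, SimulationConfig, strong_signal_config
from .enrichment import enrich_targets
from .expression import build_deg_feature_matrix, degs_from_dataset
from .simulate import simulate_activity_matrix, simulate_bundle, simulate_labels

logger = logging.getLogger(__name__)


def child_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2**31) derived from one base seed."""
    return [int(s) for s in
            np.random.SeedSequence(int(base_seed)).generate_state(n) % (2 ** 31)]


def enrichment_recovery(base_seed: int, n_seeds: int = 20, top_k: int = 10) -> dict:
    """Fraction of seeds in which every planted promoter target lands in the
    top-k of the Fisher ranking, under the strong-signal planted config."""
    hits = 0
    for s in child_seeds(base_seed, n_seeds):
        cfg = strong_signal_config(seed=s, n_genes=10, planted_degs_per_class=0,
                                   n_gene_sets=1, gene_set_size=5)
        study, background, truth = simulate_activity_matrix(cfg)
        labels = simulate_labels(cfg, truth)["label"]
        res = enrich_targets(PROMOTE, study, labels, background)
        top = set(res.head(top_k)["target_id"])
        hits += int(set(truth.promoter_targets) <= top)
    return {"recovery_rate": hits / n_seeds, "n": n_seeds}


def enrichment_null_flag_rate(base_seed: int, n_seeds: int = 20,
                              alpha: float = 0.05) -> dict:
    """Mean per-target flag rate at alpha when no target is planted (the
    phenotype set shares every rate with the background)."""
    rates = []
    for s in child_seeds(base_seed, n_seeds):
        cfg = strong_signal_config(seed=s, planted_targets_per_class=0,
                                   n_genes=10, planted_degs_per_class=0,
                                   n_gene_sets=1, gene_set_size=5)
        study, background, truth = simulate_activity_matrix(cfg)
        labels = simulate_labels(cfg, truth)["label"]
        res = enrich_targets(PROMOTE, study, labels, background)
        rates.append(float((res["p_value"] < alpha).mean()))
    return {"flag_rate": float(np.mean(rates)), "n": n_seeds}


def deg_recovery(base_seed: int, n_seeds: int = 10) -> dict:
    """Per-compound sensitivity/specificity of DEG calls for planted genes
    (planted FC 2, log2 noise 0.25, duplicate arrays), averaged over seeds."""
    sens, spec = [], []
    for s in child_seeds(base_seed, n_seeds):
        cfg = SimulationConfig(
            n_promoters=10, n_inhibitors=10, n_unknown=0, n_background=10,
            n_targets=5, planted_targets_per_class=1, n_genes=300,
            planted_degs_per_class=20, planted_fc=2.0, noise_sd=0.25,
            n_replicates=2, n_controls=4, n_gene_sets=5, gene_set_size=10, seed=s)
        bundle = simulate_bundle(cfg)
        profiles = degs_from_dataset(bundle.expression)
        planted = {PROMOTE: set(bundle.truth.promoter_genes),
                   INHIBIT: set(bundle.truth.inhibitor_genes)}
        called = profiles.deg_sets()
        universe = set(profiles.gene_universe)
        for cid in profiles.compounds:
            pos = planted[bundle.truth.true_labels[cid]]
            neg = universe - pos
            sens.append(len(called[cid] & pos) / len(pos))
            spec.append(len(neg - called[cid]) / len(neg))
    return {"sensitivity": float(np.mean(sens)), "specificity": float(np.mean(spec)),
            "n": n_seeds}


def _fused_dataset(seed: int):
    cfg = strong_signal_config(seed=seed)
    bundle = simulate_bundle(cfg)
    profiles = degs_from_dataset(bundle.expression)
    deg = build_deg_feature_matrix(profiles)
    tp = bundle.study_activity.binarize()
    labels = bundle.labels["label"]
    labelled = labels[labels != UNKNOWN]
    fm = clf.fuse_features(tp, deg, "both")
    X = fm.values.loc[fm.values.index.intersection(labelled.index)]
    return X, labelled.loc[X.index], bundle.truth


def classifier_recovery(base_seed: int, n_seeds: int = 10,
                        n_trees: int = 200) -> dict:
    """LOO AUC on the strong-signal fused dataset, the permuted-label null
    AUC, and the planted fraction of the top-10 Gini features (seed means)."""
    aucs, null_aucs, planted_fracs = [], [], []
    for s in child_seeds(base_seed, n_seeds):
        X, labels, truth = _fused_dataset(s)
        mcfg = ModelConfig(forest_n_trees=n_trees, seed=s)
        rep = clf.loo_cv(X, labels, mcfg)
        aucs.append(rep.metrics["roc_auc"])

        perm = pd.Series(np.random.default_rng(s).permutation(labels.to_numpy()),
                         index=labels.index)
        null_rep = clf.loo_cv(X, perm, mcfg)
        null_aucs.append(null_rep.metrics["roc_auc"])

        forest = clf.train_forest(X, labels, mcfg)
        top = clf.gini_top_features(forest, list(X.columns), k=10)
        planted = truth.planted_features()
        planted_fracs.append(float(np.mean([f in planted for f in top["feature"]])))
    return {"loo_auc": float(np.mean(aucs)),
            "permuted_auc": float(np.mean(null_aucs)),
            "planted_top10_fraction": float(np.mean(planted_fracs)),
            "n": n_seeds}
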