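"""Seeded synthetic datasets with planted ground truth.

The generator emulates the statistical shape of the study inputs — binary
compound × target activity bitmaps from a ligand-based target predictor, and
log2 microarray expression with duplicate arrays, multi-probe genes and
pooled DMSO controls — while planting a recoverable signal: per phenotype
class, a disjoint set of targets whose activity rate is elevated above
baseline, and a disjoint set of genes shifted by ±log2(planted_fc). Every
randomness source derives from ``cfg.seed``, so outputs are reproducible
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import INHIBIT, PROMOTE, UNKNOWN, SimulationConfig
from .enrichment import ActivityMatrix
from .expression import ExpressionDataset
from .ora import GeneSetCollection, write_gmt

logger = logging.getLogger(__name__)

CONTROL_ID = "DMSO"

# fixed stream indices for per-stage child generators
_STREAM_ACTIVITY, _STREAM_EXPRESSION, _STREAM_GENESETS, _STREAM_LABELS = 0, 1, 2, 3


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


@dataclass
class SyntheticTruth:
    """Planted ground truth: target/gene sets per class, hidden labels, signs."""

    promoter_targets: list[str]
    inhibitor_targets: list[str]
    promoter_genes: list[str]
    inhibitor_genes: list[str]
    true_labels: dict[str, str]      # compound → PROMOTE / INHIBIT (incl. unknowns)
    gene_signs: dict[str, int] = field(default_factory=dict)  # planted gene → ±1

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["gene_signs"] = {k: int(v) for k, v in data.get("gene_signs", {}).items()}
        return cls(**data)

    def planted_features(self) -> set[str]:
        """Namespaced feature ids of every planted target and gene."""
        return ({f"TP:{t}" for t in self.promoter_targets + self.inhibitor_targets}
                | {f"DEG:{g}" for g in self.promoter_genes + self.inhibitor_genes})


def _ids(prefix: str, n: int) -> list[str]:
    width = max(len(str(n)), 3)
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def compound_ids(cfg: SimulationConfig) -> tuple[list[str], list[str], list[str], list[str]]:
    """(promoters, inhibitors, unknowns, background) compound id lists."""
    return (_ids("PRO", cfg.n_promoters), _ids("INH", cfg.n_inhibitors),
            _ids("UNK", cfg.n_unknown), _ids("BKG", cfg.n_background))


def _assign_truth(cfg: SimulationConfig) -> SyntheticTruth:
    rng = _rng(cfg, _STREAM_LABELS)
    targets = _ids("T", cfg.n_targets)
    genes = _ids("G", cfg.n_genes)
    k = cfg.planted_targets_per_class
    tsel = rng.choice(cfg.n_targets, size=2 * k, replace=False) if k else np.array([], int)
    m = cfg.planted_degs_per_class
    gsel = rng.choice(cfg.n_genes, size=2 * m, replace=False) if m else np.array([], int)
    pro, inh, unk, _ = compound_ids(cfg)
    true_labels = {c: PROMOTE for c in pro}
    true_labels.update({c: INHIBIT for c in inh})
    # hidden classes of unknowns: fair Bernoulli split
    for c in unk:
        true_labels[c] = PROMOTE if rng.random() < 0.5 else INHIBIT
    planted_genes = [genes[i] for i in gsel]
    signs = {g: int(s) for g, s in zip(planted_genes,
                                       rng.choice([-1, 1], size=len(planted_genes)))}
    return SyntheticTruth(
        promoter_targets=[targets[i] for i in tsel[:k]],
        inhibitor_targets=[targets[i] for i in tsel[k:]],
        promoter_genes=planted_genes[:m],
        inhibitor_genes=planted_genes[m:],
        true_labels=true_labels,
        gene_signs=signs,
    )


def simulate_activity_matrix(cfg: SimulationConfig,
                             truth: SyntheticTruth | None = None
                             ) -> tuple[ActivityMatrix, ActivityMatrix, SyntheticTruth]:
    """Bernoulli activity bitmaps for study and background compounds.

    Every cell is Bernoulli(baseline_activity_rate) except planted targets in
    compounds of their own (hidden) class, which are Bernoulli(
    planted_activity_rate). The background is all-baseline.
    """
    truth = truth or _assign_truth(cfg)
    rng = _rng(cfg, _STREAM_ACTIVITY)
    targets = _ids("T", cfg.n_targets)
    pro, inh, unk, bkg = compound_ids(cfg)
    study_ids = pro + inh + unk

    study = rng.binomial(1, cfg.baseline_activity_rate,
                         size=(len(study_ids), cfg.n_targets))
    tpos = {t: j for j, t in enumerate(targets)}
    planted_cols = {PROMOTE: [tpos[t] for t in truth.promoter_targets],
                    INHIBIT: [tpos[t] for t in truth.inhibitor_targets]}
    for i, cid in enumerate(study_ids):
        cols = planted_cols[truth.true_labels[cid]]
        if cols:
            study[i, cols] = rng.binomial(1, cfg.planted_activity_rate, size=len(cols))
    background = rng.binomial(1, cfg.baseline_activity_rate,
                              size=(cfg.n_background, cfg.n_targets))
    study_df = pd.DataFrame(study, index=pd.Index(study_ids, name="compound_id"),
                            columns=targets)
    bkg_df = pd.DataFrame(background, index=pd.Index(bkg, name="compound_id"),
                          columns=targets)
    return ActivityMatrix(study_df), ActivityMatrix(bkg_df), truth


def simulate_expression(cfg: SimulationConfig, truth: SyntheticTruth) -> ExpressionDataset:
    """Log2 expression: gene baselines ~ N(7, 1), per-probe affinity offsets,
    replicate noise ~ N(0, noise_sd); planted genes shift by ±log2(planted_fc)
    in compounds of their class (signs as recorded in the truth)."""
    pro, inh, unk, _ = compound_ids(cfg)
    study_ids = pro + inh + unk
    missing = [c for c in study_ids if c not in truth.true_labels]
    if missing or not set(truth.promoter_genes) <= set(_ids("G", cfg.n_genes)):
        raise ValueError("cfg and truth describe different datasets")
    rng = _rng(cfg, _STREAM_EXPRESSION)
    genes = _ids("G", cfg.n_genes)
    mu = rng.normal(7.0, 1.0, size=cfg.n_genes)
    n_probes = rng.integers(1, cfg.max_probes_per_gene + 1, size=cfg.n_genes)
    probe_ids, probe_gene, probe_mu = [], [], []
    for g, gene in enumerate(genes):
        for p in range(int(n_probes[g])):
            probe_ids.append(f"{gene}_p{p + 1}")
            probe_gene.append(gene)
            probe_mu.append(mu[g] + rng.normal(0.0, 0.5))  # probe affinity
    probe_mu = np.asarray(probe_mu)
    gene_of_probe = np.asarray([int(g[1:]) - 1 for g in probe_gene])

    delta = np.log2(cfg.planted_fc)
    cls_effect = {}
    for cls, planted in ((PROMOTE, truth.promoter_genes), (INHIBIT, truth.inhibitor_genes)):
        e = np.zeros(cfg.n_genes)
        for gname in planted:
            e[int(gname[1:]) - 1] = truth.gene_signs.get(gname, 1) * delta
        cls_effect[cls] = e

    sample_ids, comp_col, rep_col, ctrl_col, columns = [], [], [], [], []
    for cid in study_ids:
        e = cls_effect[truth.true_labels[cid]][gene_of_probe]
        for r in range(1, cfg.n_replicates + 1):
            noise = rng.normal(0.0, cfg.noise_sd, size=len(probe_ids)) if cfg.noise_sd else 0.0
            columns.append(probe_mu + e + noise)
            sample_ids.append(f"{cid}_r{r}")
            comp_col.append(cid)
            rep_col.append(r)
            ctrl_col.append(False)
    for r in range(1, cfg.n_controls + 1):
        noise = rng.normal(0.0, cfg.noise_sd, size=len(probe_ids)) if cfg.noise_sd else 0.0
        columns.append(probe_mu + noise)
        sample_ids.append(f"{CONTROL_ID}_c{r}")
        comp_col.append(CONTROL_ID)
        rep_col.append(r)
        ctrl_col.append(True)

    values = pd.DataFrame(np.column_stack(columns),
                          index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids)
    samples = pd.DataFrame({"compound_id": comp_col, "replicate": rep_col,
                            "is_control": ctrl_col},
                           index=pd.Index(sample_ids, name="sample_id"))
    probe_map = pd.Series(probe_gene, index=pd.Index(probe_ids, name="probe_id"),
                          name="gene_id")
    return ExpressionDataset(values=values, samples=samples, probe_map=probe_map)


def simulate_genesets(cfg: SimulationConfig, truth: SyntheticTruth) -> GeneSetCollection:
    """Decoy gene sets plus one planted pathway per class built around the
    planted DEGs (padded with random genes to gene_set_size)."""
    rng = _rng(cfg, _STREAM_GENESETS)
    genes = _ids("G", cfg.n_genes)
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for i in range(1, cfg.n_gene_sets + 1):
        name = f"SET{i:03d}"
        members = rng.choice(cfg.n_genes, size=cfg.gene_set_size, replace=False)
        sets[name] = [genes[j] for j in sorted(members)]
        desc[name] = "random decoy set"
    for name, planted in (("PROMOTER_PATHWAY", truth.promoter_genes),
                          ("INHIBITOR_PATHWAY", truth.inhibitor_genes)):
        if not planted:
            continue
        members = list(planted)
        pool = [g for g in genes if g not in set(members)]
        pad = max(0, cfg.gene_set_size - len(members))
        if pad and pool:
            extra = rng.choice(len(pool), size=min(pad, len(pool)), replace=False)
            members += [pool[j] for j in sorted(extra)]
        sets[name] = members
        desc[name] = "planted pathway"
    return GeneSetCollection(sets=sets, descriptions=desc, universe=list(genes))


def simulate_labels(cfg: SimulationConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Observed phenotype labels: knowns (optionally flipped at
    label_flip_rate, emulating literature mislabelling), unknowns UNKNOWN."""
    rng = _rng(cfg, 4)
    pro, inh, unk, _ = compound_ids(cfg)
    rows = []
    for cid in pro + inh:
        lab = truth.true_labels[cid]
        if cfg.label_flip_rate and rng.random() < cfg.label_flip_rate:
            lab = INHIBIT if lab == PROMOTE else PROMOTE
        rows.append((cid, lab))
    rows += [(cid, UNKNOWN) for cid in unk]
    return pd.DataFrame(rows, columns=["compound_id", "label"]).set_index("compound_id")


@dataclass
class SyntheticBundle:
    """Everything one seeded simulation produces."""

    cfg: SimulationConfig
    truth: SyntheticTruth
    study_activity: ActivityMatrix
    background_activity: ActivityMatrix
    expression: ExpressionDataset
    labels: pd.DataFrame
    genesets: GeneSetCollection


def simulate_bundle(cfg: SimulationConfig) -> SyntheticBundle:
    """Generate the full dataset bundle for one config/seed."""
    study, background, truth = simulate_activity_matrix(cfg)
    expression = simulate_expression(cfg, truth)
    genesets = simulate_genesets(cfg, truth)
    labels = simulate_labels(cfg, truth)
    return SyntheticBundle(cfg=cfg, truth=truth, study_activity=study,
                           background_activity=background, expression=expression,
                           labels=labels, genesets=genesets)


def write_dataset(bundle: SyntheticBundle, out_dir: str | Path) -> dict:
    """Write the bundle as TSV/GMT/JSON files; returns a manifest of files
    with their row/column counts. The directory is created if missing."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    def _tsv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t")
        manifest[name] = {"rows": int(df.shape[0]), "cols": int(df.shape[1])}

    _tsv(bundle.expression.values, "expression.tsv")
    _tsv(bundle.expression.samples, "samples.tsv")
    _tsv(bundle.expression.probe_map.to_frame(), "probe_map.tsv")
    _tsv(bundle.study_activity.values, "targets_study.tsv")
    _tsv(bundle.background_activity.values, "targets_background.tsv")
    _tsv(bundle.labels, "labels.tsv")
    write_gmt(bundle.genesets, out / "genesets.gmt")
    manifest["genesets.gmt"] = {"rows": len(bundle.genesets.sets), "cols": 0}
    bundle.truth.to_json(out / "truth.json")
    manifest["truth.json"] = {"rows": len(bundle.truth.true_labels), "cols": 0}
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(bundle.cfg), fh, sort_keys=True)
    manifest["sim_config.yaml"] = {"rows": len(dataclasses.fields(bundle.cfg)), "cols": 0}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
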