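"""Microarray expression processing: from probe-level log2 intensities to
per-compound differentially-expressed-gene (DEG) calls.

The processing chain mirrors standard two-colourless microarray practice:
quantile normalization across arrays, collapse of multi-probe genes by
maximum, averaging of replicate arrays, then fold-change calling against the
pooled vehicle (DMSO) control at a linear 1.5-fold threshold (boundary
inclusive, both directions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEGConfig

logger = logging.getLogger(__name__)

# tolerance for boundary-inclusive fold-change comparisons: a ratio that is
# exactly the threshold must not be lost to one ulp of log2 round-off
_EPS = 1e-12


@dataclass
class ExpressionDataset:
    """Probe-level log2 expression with its sample sheet and probe→gene map.

    values:    probes × samples DataFrame of log2 intensities
    samples:   DataFrame indexed by sample_id with columns
               (compound_id, replicate, is_control)
    probe_map: Series probe_id → gene_id
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    probe_map: pd.Series

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        sheet = list(self.samples.index)
        if sorted(cols) != sorted(sheet) or len(set(cols)) != len(cols):
            raise ValueError("every sample column must appear exactly once in the sample sheet")
        if int(self.samples["is_control"].sum()) < 2:
            raise ValueError("at least 2 control samples are required")
        unmapped = self.values.index.difference(self.probe_map.index)
        if len(unmapped):
            logger.info("dropping %d probes without a gene mapping", len(unmapped))
            self.values = self.values.drop(index=unmapped)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def compounds(self) -> list[str]:
        mask = ~self.samples["is_control"].astype(bool)
        return sorted(self.samples.loc[mask, "compound_id"].unique())


@dataclass
class DEGProfiles:
    """Per-compound DEG calls and the derived binary feature matrix.

    table: long DataFrame (compound_id, gene_id, direction, fold_change) with
           direction in {"up", "down"} and fold_change on the linear scale.
    gene_universe: every gene that was tested (collapsed platform genes).
    compounds: every compound that was tested, including those with no DEGs.
    """

    table: pd.DataFrame
    gene_universe: list[str]
    compounds: list[str]
    fc_threshold: float = 1.5

    def __post_init__(self) -> None:
        dup = self.table.duplicated(subset=["compound_id", "gene_id"])
        if dup.any():
            raise ValueError("a gene may appear at most once per compound")
        if len(self.table):
            lo = np.log2(self.fc_threshold) - 1e-9  # looser than call-time eps: 2**log2 round trip
            if (np.abs(np.log2(self.table["fold_change"].to_numpy())) < lo).any():
                raise ValueError("recorded fold changes must meet the threshold")

    def deg_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {c: set() for c in self.compounds}
        for cid, g in zip(self.table["compound_id"], self.table["gene_id"]):
            out[cid].add(g)
        return out

    def to_matrix(self, signed: bool = False) -> pd.DataFrame:
        return build_deg_feature_matrix(self, signed=signed)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean-of-order-statistics reference.

    After normalization every column holds the identical multiset of values
    (the per-rank means of the sorted columns) while within-column ranks are
    preserved. Ties are assigned in stable sort order.
    """
    if matrix.shape[1] < 1:
        raise ValueError("need at least one column")
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing values present; impute upstream before normalization")
    order = np.argsort(vals, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(vals.shape[0])
    for j in range(vals.shape[1]):
        ranks[order[:, j], j] = rows
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = ref[ranks]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(dataset: ExpressionDataset, cfg: DEGConfig,
                    values: pd.DataFrame | None = None) -> pd.DataFrame:
    """Collapse probe rows to one row per gene.

    ``per_sample_max`` takes the element-wise maximum over a gene's probes in
    each sample; ``max_mean_probe`` keeps the single probe with the highest
    mean across all samples (ties broken by probe id). ``values`` overrides
    the dataset's matrix, e.g. to pass the quantile-normalized one.
    """
    mat = dataset.values if values is None else values
    genes = dataset.probe_map.reindex(mat.index)
    keep = genes.notna()
    if (~keep).any():
        logger.info("collapse: dropping %d unmapped probes", int((~keep).sum()))
        mat, genes = mat.loc[keep], genes.loc[keep]
    if cfg.collapse_mode == "per_sample_max":
        collapsed = mat.groupby(genes.to_numpy()).max()
    else:  # max_mean_probe
        means = mat.mean(axis=1)
        # per gene keep the probe with the largest mean; ties → smaller probe id
        best: dict[str, tuple[str, float]] = {}
        for probe, gene, mean in zip(mat.index, genes, means):
            cur = best.get(gene)
            if cur is None or mean > cur[1] or (mean == cur[1] and probe < cur[0]):
                best[gene] = (probe, mean)
        picked = [best[g][0] for g in sorted(best)]
        collapsed = mat.loc[picked]
        collapsed.index = sorted(best)
    collapsed.index.name = "gene_id"
    return collapsed.sort_index()


def average_replicates(gene_matrix: pd.DataFrame,
                       samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Average replicate arrays per compound; pool all controls into one mean.

    Returns (compounds × genes means, pooled control mean over genes).
    """
    samples = samples.loc[gene_matrix.columns]
    is_ctrl = samples["is_control"].astype(bool)
    if int(is_ctrl.sum()) < 1:
        raise ValueError("no control samples present")
    control_mean = gene_matrix.loc[:, is_ctrl[is_ctrl].index].mean(axis=1)
    treated = samples.loc[~is_ctrl]
    rows = {}
    for cid, grp in treated.groupby("compound_id", sort=True):
        cols = list(grp.index)
        if not cols:
            raise ValueError(f"compound {cid} has no samples")
        rows[cid] = gene_matrix[cols].mean(axis=1)
    if not rows:
        raise ValueError("no treated samples present")
    means = pd.DataFrame(rows).T
    means.index.name = "compound_id"
    return means, control_mean


def call_degs(compound_means: pd.DataFrame, control_mean: pd.Series,
              cfg: DEGConfig) -> DEGProfiles:
    """Call per-compound DEGs against the pooled control at cfg.fc_threshold.

    A gene is up if log2(treated) − log2(control) ≥ log2(threshold), down if
    ≤ −log2(threshold); the boundary is inclusive. fold_change is reported on
    the linear scale (down-regulated genes have fold_change < 1).
    """
    if list(compound_means.columns) != list(control_mean.index):
        control_mean = control_mean.reindex(compound_means.columns)
        if control_mean.isna().any():
            raise ValueError("compound and control gene universes differ")
    if cfg.scale == "linear_input":
        if (compound_means.to_numpy() <= 0).any() or (control_mean.to_numpy() <= 0).any():
            raise ValueError("linear_input requires strictly positive intensities")
        diff = np.log2(compound_means) - np.log2(control_mean)
    else:
        diff = compound_means - control_mean
    cut = np.log2(cfg.fc_threshold) - _EPS
    records = []
    genes = np.asarray(compound_means.columns)
    for cid in compound_means.index:
        d = diff.loc[cid].to_numpy()
        up, down = d >= cut, d <= -cut
        for g, v in zip(genes[up], d[up]):
            records.append((cid, g, "up", float(2.0 ** v)))
        for g, v in zip(genes[down], d[down]):
            records.append((cid, g, "down", float(2.0 ** v)))
    table = pd.DataFrame(records, columns=["compound_id", "gene_id", "direction", "fold_change"])
    return DEGProfiles(table=table, gene_universe=list(compound_means.columns),
                       compounds=list(compound_means.index), fc_threshold=cfg.fc_threshold)


def build_deg_feature_matrix(profiles: DEGProfiles, signed: bool = False) -> pd.DataFrame:
    """Binary (or signed {-1, 0, +1}) compounds × genes dysregulation matrix.

    Column order is the recorded gene universe; row order the recorded
    compound list, so the encoding is stable across runs.
    """
    mat = pd.DataFrame(0, index=pd.Index(profiles.compounds, name="compound_id"),
                       columns=pd.Index(profiles.gene_universe, name="gene_id"),
                       dtype=int)
    for cid, gid, direction in zip(profiles.table["compound_id"],
                                   profiles.table["gene_id"],
                                   profiles.table["direction"]):
        mat.at[cid, gid] = (-1 if (signed and direction == "down") else 1)
    return mat


def degs_from_dataset(dataset: ExpressionDataset, cfg: DEGConfig | None = None,
                      normalize: bool = True) -> DEGProfiles:
    """Full chain: quantile-normalize → collapse probes → average replicates →
    call DEGs. The standard entry point for probe-level data."""
    cfg = cfg or DEGConfig()
    values = quantile_normalize(dataset.values) if normalize else dataset.values
    genes = collapse_probes(dataset, cfg, values=values)
    means, control = average_replicates(genes, dataset.samples)
    return call_degs(means, control, cfg)
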