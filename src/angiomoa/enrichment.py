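"""Phenotype-directed target enrichment against a background chemical space.

For each predicted protein target, compounds with a given phenotype label
(PROMOTE or INHIBIT) are compared with a large background compound set that
is treated as putatively phenotype-inactive. The 2×2 table per target is

    a  phenotype-set compounds predicted active
    b  phenotype-set compounds predicted inactive
    c  background compounds predicted active
    d  background compounds predicted inactive

and the enrichment statistic is the prevalence ratio

    OR = (a / (a + b)) / (c / (c + d)),

reported here under its original name "odds ratio" together with the textbook
odds ratio a·d / (b·c) as a secondary column. Significance is a Fisher exact
p-value; targets are ranked ascending by p. Compound bioactivity profiles over
the enriched targets can then be hierarchically clustered into putative
mode-of-action groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats

from .config import INHIBIT, PROMOTE, EnrichmentConfig

logger = logging.getLogger(__name__)


@dataclass
class ActivityMatrix:
    """Compounds × protein targets predicted-activity matrix.

    Values may be binary or probabilities in [0, 1]; probabilistic input is
    binarized at ``activity_cutoff`` (a value exactly at the cutoff is active).
    """

    values: pd.DataFrame
    activity_cutoff: float = 0.5

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if ((v < 0) | (v > 1)).any():
            raise ValueError("activity values must lie in [0, 1]")
        if self.values.index.has_duplicates:
            raise ValueError("compound identifiers must be unique")
        if self.values.columns.has_duplicates:
            raise ValueError("target identifiers must be unique")

    @property
    def compounds(self) -> pd.Index:
        return self.values.index

    @property
    def targets(self) -> pd.Index:
        return self.values.columns

    def binarize(self) -> pd.DataFrame:
        return binarize(self)


def binarize(matrix: ActivityMatrix) -> pd.DataFrame:
    """Threshold probabilistic activities; already-binary input is unchanged."""
    v = matrix.values.to_numpy(dtype=float)
    out = (v >= matrix.activity_cutoff).astype(int)
    return pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)


@dataclass(frozen=True)
class ContingencyTable:
    """Active/inactive counts in the phenotype set (a, b) and background (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def phenotype_size(self) -> int:
        return self.a + self.b

    @property
    def background_size(self) -> int:
        return self.c + self.d


def build_contingency(target_id: str, phenotype_compounds: list[str],
                      study: pd.DataFrame, background: pd.DataFrame) -> ContingencyTable:
    """Count active/inactive predictions for one target (binary matrices)."""
    if len(phenotype_compounds) == 0:
        raise ValueError("phenotype set is empty")
    if background.shape[0] == 0:
        raise ValueError("background set is empty")
    if target_id not in study.columns or target_id not in background.columns:
        raise KeyError(f"target {target_id!r} absent from study or background matrix")
    col = study.loc[phenotype_compounds, target_id]
    a = int(col.sum())
    b = len(phenotype_compounds) - a
    c = int(background[target_id].sum())
    d = background.shape[0] - c
    return ContingencyTable(a, b, c, d)


def odds_ratio(t: ContingencyTable) -> float:
    """The prevalence-ratio enrichment statistic (a/(a+b)) / (c/(c+d)).

    Returns +inf when the background rate is zero but the phenotype rate is
    not, 0.0 for the converse, and NaN (undefined) when both rates are zero.
    """
    if t.phenotype_size == 0 or t.background_size == 0:
        raise ValueError("both margins must be nonempty")
    if t.c == 0:
        if t.a == 0:
            return math.nan
        return math.inf
    return (t.a / t.phenotype_size) / (t.c / t.background_size)


def textbook_odds_ratio(t: ContingencyTable) -> float:
    """The classical cross-product odds ratio a·d / (b·c), same sentinels."""
    if t.phenotype_size == 0 or t.background_size == 0:
        raise ValueError("both margins must be nonempty")
    if t.b * t.c == 0:
        if t.a * t.d == 0:
            return math.nan
        return math.inf
    return (t.a * t.d) / (t.b * t.c)


def fisher_exact_p(t: ContingencyTable, sidedness: str = "two-sided") -> float:
    """Fisher exact p for the 2×2 table.

    Two-sided: sum of point probabilities of all tables (at fixed margins) no
    more probable than the observed one. One-sided "greater": tables with
    a' >= a. Computed in log space internally (scipy), so large background
    margins never overflow.
    """
    if sidedness not in ("two-sided", "greater"):
        raise ValueError("sidedness must be 'two-sided' or 'greater'")
    alternative = "two-sided" if sidedness == "two-sided" else "greater"
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative=alternative)
    return float(min(p, 1.0))


def enrich_targets(phenotype: str, study: ActivityMatrix, labels: pd.Series,
                   background: ActivityMatrix,
                   cfg: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Rank every target by Fisher exact p for one phenotype class.

    ``labels`` maps compound_id → {PROMOTE, INHIBIT, UNKNOWN}; only compounds
    labelled ``phenotype`` enter the 2×2 tables. Returns a DataFrame sorted
    ascending by p_value (ties: descending odds_ratio, then target id) with
    columns target_id, a, b, c, d, odds_ratio, textbook_or, p_value,
    significant (p < cfg.alpha).
    """
    cfg = cfg or EnrichmentConfig()
    if phenotype not in (PROMOTE, INHIBIT):
        raise ValueError(f"phenotype must be {PROMOTE} or {INHIBIT}")
    diff = study.targets.symmetric_difference(background.targets)
    if len(diff):
        raise ValueError(f"study and background target universes differ: {sorted(diff)}")
    members = [c for c in study.compounds if labels.get(c) == phenotype]
    if not members:
        raise ValueError(f"no compounds labelled {phenotype}")
    sb = binarize(study)
    bb = binarize(background)
    rows = []
    for tid in study.targets:
        t = build_contingency(tid, members, sb, bb)
        rows.append({
            "target_id": tid, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "odds_ratio": odds_ratio(t),
            "textbook_or": textbook_odds_ratio(t),
            "p_value": fisher_exact_p(t, cfg.sidedness),
        })
    res = pd.DataFrame(rows)
    res["significant"] = res["p_value"] < cfg.alpha
    # ascending p; ties broken by descending OR (inf first), then target id
    res = res.sort_values(["p_value", "odds_ratio", "target_id"],
                          ascending=[True, False, True], kind="stable",
                          na_position="last")
    return res.reset_index(drop=True)


@dataclass
class ClusterResult:
    """Hierarchical-clustering output for a compounds × features profile matrix."""

    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    row_clusters: pd.Series | None = None  # compound → cluster id when k given


def cluster_profiles(matrix: pd.DataFrame, metric: str = "euclidean",
                     linkage: str = "average", k: int | None = None) -> ClusterResult:
    """Agglomerative clustering of profile rows (and columns), deterministic
    given input order. ``k`` cuts the row dendrogram into k flat clusters."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    vals = matrix.to_numpy(dtype=float)
    if np.allclose(vals, vals.flat[0]):
        logger.warning("constant profile matrix: all rows fall in a single cluster")
    rd = ssd.pdist(vals, metric=metric)
    row_link = sch.linkage(rd, method=linkage)
    row_order = [matrix.index[i] for i in sch.leaves_list(row_link)]
    col_link = None
    col_order = list(matrix.columns)
    if matrix.shape[1] >= 2:
        cd = ssd.pdist(vals.T, metric=metric)
        col_link = sch.linkage(cd, method=linkage)
        col_order = [matrix.columns[i] for i in sch.leaves_list(col_link)]
    clusters = None
    if k is not None:
        flat = sch.fcluster(row_link, t=k, criterion="maxclust")
        clusters = pd.Series(flat, index=matrix.index, name="cluster")
    return ClusterResult(row_order=row_order, col_order=col_order,
                         row_linkage=row_link, col_linkage=col_link,
                         row_clusters=clusters)
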