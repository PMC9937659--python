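"""Per-compound pathway over-representation analysis (ORA).

Each compound's DEG list is tested against every gene set of a GMT collection
with the upper-tail hypergeometric test, p-values are Benjamini–Hochberg
adjusted within that compound's family of tests, and the cross-compound
recurrence filter keeps only sets significant (adjusted p ≤ alpha) in at
least ``min_compounds`` compounds — the matrix behind the pathway heatmap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ORAConfig
from .expression import DEGProfiles

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background gene universe.

    sets: name → member gene list (unique, nonempty)
    descriptions: name → free-text description
    universe: background gene ids; members outside it are dropped (logged).
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("universe gene ids must be unique")
        for name, members in list(self.sets.items()):
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            kept = [g for g in members if g in uni]
            dropped = len(members) - len(kept)
            if dropped:
                logger.info("gene set %s: dropped %d members outside the universe",
                            name, dropped)
            if not kept:
                logger.warning("gene set %s has no members in the universe; removed", name)
                del self.sets[name]
                self.descriptions.pop(name, None)
            else:
                self.sets[name] = kept

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path, universe: list[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name <TAB> description <TAB> gene...).

    Duplicate genes within a set are deduplicated with a warning; malformed
    lines and duplicate set names raise with the line number. If ``universe``
    is omitted, the union of all members is used.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}: "
                                 "expected name, description and >=1 gene")
            name, desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}: malformed GMT line {lineno}: empty gene set")
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning("gene set %s lists %d duplicate gene(s); deduplicated",
                               name, len(genes) - len(unique))
            sets[name] = unique
            descriptions[name] = desc
    if universe is None:
        universe = sorted({g for members in sets.values() for g in members})
    return GeneSetCollection(sets=sets, descriptions=descriptions, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def ora_hypergeometric(deg_list: list[str] | set[str], gene_set: list[str] | set[str],
                       universe: list[str] | set[str]) -> dict:
    """Upper-tail hypergeometric test P(X >= x) of DEG/gene-set overlap.

    N = |universe|, K = |gene_set ∩ universe|, n = |deg_list ∩ universe|,
    x = |deg_list ∩ gene_set ∩ universe|. Genes outside the universe are
    dropped (logged). Returns overlap stats and the p-value.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    degs = set(deg_list)
    outside = degs - uni
    if outside:
        logger.info("ORA: dropped %d DEGs outside the universe", len(outside))
        degs &= uni
    gset = set(gene_set) & uni
    x = len(degs & gset)
    N, K, n = len(uni), len(gset), len(degs)
    p = float(stats.hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
    return {"overlap": x, "set_size": K, "list_size": n, "universe_size": N,
            "p_value": min(max(p, 0.0), 1.0)}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(profiles: DEGProfiles, collection: GeneSetCollection,
            cfg: ORAConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ORA for every (compound, gene set) pair plus the recurrence-filtered
    pathway × compound matrix.

    BH adjustment is applied within each compound's family of tested sets.
    The matrix keeps sets with adjusted_p <= cfg.alpha in >= cfg.min_compounds
    compounds; cells carry −log10(adjusted_p). Compounds with an empty DEG
    list get p = 1 for every set (warning).
    """
    cfg = cfg or ORAConfig()
    deg_sets = profiles.deg_sets()
    if not any(deg_sets.values()):
        raise ValueError("no compound has a nonempty DEG list")
    names = collection.names
    records = []
    for cid in profiles.compounds:
        degs = deg_sets.get(cid, set())
        if not degs:
            logger.warning("compound %s has an empty DEG list; all p = 1", cid)
        stats_rows = [ora_hypergeometric(degs, collection.sets[s], collection.universe)
                      for s in names]
        adj = bh_adjust([r["p_value"] for r in stats_rows])
        for s, r, ap in zip(names, stats_rows, adj):
            records.append({"compound_id": cid, "set_name": s, **r,
                            "adjusted_p": float(ap)})
    results = pd.DataFrame(records)
    sig = results[results["adjusted_p"] <= cfg.alpha]
    counts = sig.groupby("set_name")["compound_id"].nunique()
    retained = sorted(counts[counts >= cfg.min_compounds].index)
    sub = results[results["set_name"].isin(retained)]
    matrix = (sub.pivot(index="set_name", columns="compound_id", values="adjusted_p")
              if len(sub) else pd.DataFrame(index=pd.Index([], name="set_name")))
    matrix = (-np.log10(matrix) + 0.0) if matrix.size else matrix  # +0.0 kills -0.0
    return results, matrix
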