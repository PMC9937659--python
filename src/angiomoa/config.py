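"""Configuration objects for every pipeline stage.

All configs are plain dataclasses validated eagerly (``__post_init__``), so a
bad value fails at construction time with the offending field named, and they
round-trip losslessly through dict/YAML for the pipeline's config echo.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

PROMOTE = "PROMOTE"
INHIBIT = "INHIBIT"
UNKNOWN = "UNKNOWN"


class ConfigError(ValueError):
    """Raised when a configuration field fails validation."""


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass
class SimulationConfig:
    """Parameters of the planted-truth synthetic dataset.

    Defaults mirror the study design the generator emulates: 19 promoter and
    32 inhibitor compounds with literature phenotype labels, 49 compounds of
    unknown phenotype, a background chemical space of 4,041 molecules, log2
    microarray expression profiled in duplicate against pooled DMSO controls.
    """

    n_promoters: int = 19
    n_inhibitors: int = 32
    n_unknown: int = 49
    n_background: int = 4041
    n_targets: int = 200
    planted_targets_per_class: int = 5
    baseline_activity_rate: float = 0.05
    planted_activity_rate: float = 0.6
    n_genes: int = 500
    max_probes_per_gene: int = 3
    planted_degs_per_class: int = 20
    planted_fc: float = 2.0       # linear fold change of planted genes
    noise_sd: float = 0.25        # log2-intensity replicate noise
    n_replicates: int = 2
    n_controls: int = 4
    label_flip_rate: float = 0.0  # literature mislabelling noise
    n_gene_sets: int = 50         # random decoy gene sets in the GMT
    gene_set_size: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_promoters", "n_inhibitors", "n_unknown", "n_background",
                     "n_targets", "planted_targets_per_class", "n_genes",
                     "max_probes_per_gene", "planted_degs_per_class",
                     "n_gene_sets", "gene_set_size"):
            _check(int(getattr(self, name)) >= 0, name, "must be a nonnegative count")
        for name in ("baseline_activity_rate", "planted_activity_rate", "label_flip_rate"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, "must be a probability in [0, 1]")
        _check(self.planted_targets_per_class == 0
               or self.planted_activity_rate > self.baseline_activity_rate,
               "planted_activity_rate", "must exceed baseline_activity_rate")
        _check(self.planted_fc > 1.0, "planted_fc", "must be a linear fold change > 1")
        _check(self.noise_sd >= 0.0, "noise_sd", "must be >= 0")
        _check(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _check(self.n_controls >= 2, "n_controls", "must be >= 2")
        _check(self.max_probes_per_gene >= 1, "max_probes_per_gene", "must be >= 1")
        _check(self.n_promoters >= 1, "n_promoters", "must be >= 1")
        _check(self.n_inhibitors >= 1, "n_inhibitors", "must be >= 1")
        _check(2 * self.planted_targets_per_class <= self.n_targets,
               "planted_targets_per_class", "two disjoint planted sets must fit in n_targets")
        _check(2 * self.planted_degs_per_class <= self.n_genes,
               "planted_degs_per_class", "two disjoint planted gene sets must fit in n_genes")
        _check(self.gene_set_size <= max(self.n_genes, 1),
               "gene_set_size", "cannot exceed n_genes")


def strong_signal_config(seed: int = 0, **overrides: Any) -> SimulationConfig:
    """Benchmark config with strong, easily recoverable planted signal.

    20 promoters and 30 inhibitors against a 4,000-compound background and
    200 targets, 5 planted targets per class active at rate 0.6 versus a 0.05
    baseline, planted 2-fold expression changes at 0.25 log2 noise.
    """
    params: dict[str, Any] = dict(
        n_promoters=20, n_inhibitors=30, n_unknown=0, n_background=4000,
        n_targets=200, planted_targets_per_class=5,
        baseline_activity_rate=0.05, planted_activity_rate=0.6,
        n_genes=500, planted_degs_per_class=20, planted_fc=2.0,
        noise_sd=0.25, n_replicates=2, n_controls=4, seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class DEGConfig:
    """Differential-expression calling parameters.

    fc_threshold is the conventional linear fold change (default 1.5);
    calls are made on the log2 scale with threshold |log2 FC| >= log2(1.5),
    boundary inclusive.
    """

    fc_threshold: float = 1.5
    collapse_mode: str = "per_sample_max"   # or "max_mean_probe"
    scale: str = "log2_input"               # or "linear_input"

    def __post_init__(self) -> None:
        _check(self.fc_threshold > 1.0, "fc_threshold", "must be > 1")
        _check(self.collapse_mode in ("per_sample_max", "max_mean_probe"),
               "collapse_mode", "must be 'per_sample_max' or 'max_mean_probe'")
        _check(self.scale in ("log2_input", "linear_input"),
               "scale", "must be 'log2_input' or 'linear_input'")


@dataclass
class EnrichmentConfig:
    """Target-enrichment options: Fisher sidedness and binarization cutoff."""

    sidedness: str = "two-sided"   # or "greater"
    activity_cutoff: float = 0.5
    alpha: float = 0.05
    top_k: int = 10
    cluster_metric: str = "euclidean"  # "jaccard" available for binary profiles
    cluster_linkage: str = "average"

    def __post_init__(self) -> None:
        _check(self.sidedness in ("two-sided", "greater"),
               "sidedness", "must be 'two-sided' or 'greater'")
        _check(0.0 <= self.activity_cutoff <= 1.0, "activity_cutoff", "must be in [0, 1]")
        _check(0.0 < self.alpha < 1.0, "alpha", "must be in (0, 1)")
        _check(self.top_k >= 1, "top_k", "must be >= 1")


@dataclass
class ORAConfig:
    """Over-representation analysis options."""

    alpha: float = 0.05           # retention cut on BH-adjusted p (inclusive)
    min_compounds: int = 2        # recurrence filter: significant in >= this many

    def __post_init__(self) -> None:
        _check(0.0 < self.alpha <= 1.0, "alpha", "must be in (0, 1]")
        _check(self.min_compounds >= 1, "min_compounds", "must be >= 1")


@dataclass
class ModelConfig:
    """Hyperparameters of the interpretable tree and predictive forest."""

    tree_max_depth: int = 20
    tree_min_samples_leaf: int = 4
    tree_criterion: str = "entropy"
    class_weighting: str = "balanced"
    forest_n_trees: int = 2000
    promoter_threshold: float = 0.4   # operating probability cut for PROMOTE
    top_k_features: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.tree_max_depth >= 1, "tree_max_depth", "must be >= 1")
        _check(self.tree_min_samples_leaf >= 1, "tree_min_samples_leaf", "must be >= 1")
        _check(self.forest_n_trees >= 1, "forest_n_trees", "must be >= 1")
        _check(0.0 < self.promoter_threshold < 1.0, "promoter_threshold", "must be in (0, 1)")
        _check(self.top_k_features >= 1, "top_k_features", "must be >= 1")


@dataclass
class PipelineConfig:
    """Bundle of all stage configs plus the global seed.

    The effective config of every run is echoed into the output directory
    and can be reloaded with :func:`load_pipeline_config`.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    degs: DEGConfig = field(default_factory=DEGConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    ora: ORAConfig = field(default_factory=ORAConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_SECTIONS = {
    "simulation": SimulationConfig,
    "degs": DEGConfig,
    "enrichment": EnrichmentConfig,
    "ora": ORAConfig,
    "model": ModelConfig,
}


def pipeline_config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    """Build a PipelineConfig from a nested dict, rejecting unknown keys."""
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        if section in data:
            sub = data.pop(section)
            if not isinstance(sub, dict):
                raise ConfigError(f"{section}: expected a mapping")
            known = {f.name for f in dataclasses.fields(cls)}
            bad = set(sub) - known
            if bad:
                raise ConfigError(f"{section}: unknown keys {sorted(bad)}")
            kwargs[section] = cls(**sub)
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    if data:
        raise ConfigError(f"unknown top-level keys {sorted(data)}")
    return PipelineConfig(**kwargs)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return pipeline_config_from_dict(data)


def save_pipeline_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
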