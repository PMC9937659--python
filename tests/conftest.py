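import numpy as np
import pytest

import angiomoa as am


def tiny_config(seed: int = 0, **overrides) -> am.SimulationConfig:
    """A small but structurally complete simulation config for fast tests."""
    params = dict(
        n_promoters=6, n_inhibitors=8, n_unknown=5, n_background=200,
        n_targets=30, planted_targets_per_class=3,
        baseline_activity_rate=0.05, planted_activity_rate=0.7,
        n_genes=80, max_probes_per_gene=3, planted_degs_per_class=8,
        planted_fc=2.0, noise_sd=0.2, n_replicates=2, n_controls=3,
        n_gene_sets=8, gene_set_size=10, seed=seed,
    )
    params.update(overrides)
    return am.SimulationConfig(**params)


@pytest.fixture(scope="session")
def tiny_cfg() -> am.SimulationConfig:
    return tiny_config(seed=0)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cfg) -> am.SyntheticBundle:
    return am.simulate_bundle(tiny_cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230203)
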