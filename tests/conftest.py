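import numpy as np
import pytest

import omnirank as o


@pytest.fixture(scope="session")
def small_cohort():
    """120-gene, 2-layer cohort with a 10-gene planted module (effect 2)."""
    cfg = o.SimConfig(
        n_genes=120, planted_genes=10, n_layers=2, effect_size=2.0, seed=11
    )
    return o.simulate(cfg)


@pytest.fixture(scope="session")
def small_stage(small_cohort):
    """Network stage (normalized layers, t stats, quartet, network, real)."""
    from omnirank.pipeline import build_network_stage, normalize_layers

    cfg = o.PipelineConfig(sim=small_cohort.config, network={"top_n": 20})
    norm = normalize_layers(small_cohort.layers, cfg)
    return build_network_stage(norm, small_cohort.labels, small_cohort.edges, 20)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
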