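import numpy as np
import pytest

from qtlbsa import SimConfig, QtlSpec, select_pools, simulate_cross, simulate_pool_reads


@pytest.fixture(scope="session")
def small_cross():
    """A modest cross with a planted QTL, shared across read-only tests."""
    cfg = SimConfig(
        n_progeny=160,
        chromosomes=[("chr1", 4_000_000), ("chr2", 4_000_000)],
        marker_density=60,
        qtl=QtlSpec("chr1", 2_000_000, 1.0),
        h2=0.6,
        pool_size=25,
        depth_mean=40,
        seed=11,
    )
    truth = simulate_cross(cfg)
    select_pools(truth)
    sites = simulate_pool_reads(truth)
    return cfg, truth, sites


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_402)
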