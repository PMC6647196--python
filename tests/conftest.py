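import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.data_too_large,
        HealthCheck.filter_too_much,
        HealthCheck.large_base_example,
    ],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_f2_scan():
    """One simulated F2 pooled-sequencing experiment at reduced size."""
    from bsamap.simulate import (
        SimulationConfig,
        make_pools,
        simulate_pool_depths,
        simulate_population,
    )

    cfg = SimulationConfig(n_individuals=1000, n_sites=1500, seed=42)
    pop = simulate_population(cfg)
    pools = make_pools(pop, cfg.pool_size, seed=cfg.seed)
    sites = simulate_pool_depths(pop, pools, cfg)
    return cfg, pop, pools, sites
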