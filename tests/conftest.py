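import numpy as np
import pytest

from landgen import synthdata as sd


@pytest.fixture(scope="session")
def small_sim():
    """One small seeded simulation shared by read-only tests."""
    cfg = sd.SimConfig(
        n_individuals=160,
        n_sites=120,
        n_neutral=400,
        n_adaptive=10,
        grid_shape=(20, 30),
        seed=101,
    )
    g, sites, env, truth = sd.simulate(cfg)
    return {"config": cfg, "g": g, "sites": sites, "env": env, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
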