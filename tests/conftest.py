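import numpy as np
import pytest
from hypothesis import settings

import trophicmeta as tm

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_web():
    """A fixed retained web used across modules (S=12, C=0.15)."""
    return tm.generate_niche_web(12, 0.15, np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_meta(small_web):
    """A fixed metacommunity on the default landscape (N=10, radius 0.32)."""
    rng = np.random.default_rng(12)
    space = tm.generate_rgg(10, 0.32, rng)
    params = tm.sample_patch_params(small_web, 10, rng)
    return tm.Metacommunity(
        web=small_web, space=space, params=params,
        dispersal=tm.DispersalRule(d=0.1, z=0.5), seed=12,
    )


def chain_web(adj: np.ndarray) -> tm.FoodWebTopology:
    """Build a FoodWebTopology by hand from a feeding matrix."""
    adj = np.asarray(adj, dtype=bool)
    S = adj.shape[0]
    web = tm.FoodWebTopology(
        S=S,
        C_target=adj.mean(),
        niche_values=np.linspace(0.1, 0.9, S),
        feeding=adj,
        trophic_position=tm.trophic_positions(adj),
    )
    return tm.assign_allometry(web, R=42.0)
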