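import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from naivetcr.prediction import (
    DESK_POOL_ALPHA,
    DESK_POOL_BETA,
    ChainPool,
)
from naivetcr.synthetic import sample_chain_pool
from naivetcr.vdj import Segment, SyntheticVDJModel, default_model

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def alpha_model():
    return default_model("alpha")


@pytest.fixture(scope="session")
def beta_model():
    return default_model("beta")


@pytest.fixture(scope="session")
def tiny_model():
    """Small exhaustively enumerable model: 2 V x 2 J, <= 2 deletions,
    <= 2 insertions."""
    return SyntheticVDJModel(
        locus="alpha",
        v_segments=[Segment("V1", "TGTGC", 0.7), Segment("V2", "TGTCC", 0.3)],
        j_segments=[Segment("J1", "GGTTC", 0.6), Segment("J2", "ACTTC", 0.4)],
        deletion_probs=[0.5, 0.3, 0.2],
        insertion_probs=[0.5, 0.3, 0.2],
        base_probs=[0.25, 0.25, 0.25, 0.25],
    )


@pytest.fixture(scope="session")
def small_pools(alpha_model, beta_model):
    """Moderate chain pools for unit-level prediction tests."""
    rng = np.random.default_rng(0)
    return {
        "alpha": ChainPool(sample_chain_pool(alpha_model, None, 30_000, rng), "alpha"),
        "beta": ChainPool(sample_chain_pool(beta_model, None, 50_000, rng), "beta"),
    }


@pytest.fixture(scope="session")
def desk_pools(alpha_model, beta_model):
    """Full desk-scale chain pools shared by the acceptance tests."""
    rng = np.random.default_rng(0)
    return {
        "alpha": ChainPool(
            sample_chain_pool(alpha_model, None, DESK_POOL_ALPHA, rng), "alpha"
        ),
        "beta": ChainPool(
            sample_chain_pool(beta_model, None, DESK_POOL_BETA, rng), "beta"
        ),
    }
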