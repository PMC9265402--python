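import logging

import numpy as np
import pandas as pd
import pytest

import aceindex as ai

# the sampler warns when a short diagnostic chain fails the Geweke screen;
# that is expected for the deliberately short chains used in unit tests
logging.getLogger("aceindex.bayes").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study shared by structural tests."""
    cfg = ai.SimConfig(n_tracts=60, n_participants=400, seed=3)
    tracts = ai.generate_tracts(cfg)
    participants, truth = ai.generate_participants(tracts, cfg)
    return cfg, tracts, participants, truth


@pytest.fixture()
def standardized_matrix(rng):
    raw = pd.DataFrame(
        rng.standard_normal((120, 6)), columns=[f"v{i}" for i in range(6)]
    )
    return ai.standardize(raw)


def two_block_matrix(seed: int = 42, n: int = 2000) -> pd.DataFrame:
    """Two independent 6-variable latent blocks plus four variables unrelated
    to either block (weak pairwise structure only, so no off-block component
    can gather four high loadings)."""
    r = np.random.default_rng(seed)
    f1, f2 = r.standard_normal(n), r.standard_normal(n)
    cols = {}
    for i in range(6):
        cols[f"b1_{i}"] = f1 + 0.3 * r.standard_normal(n)
    for i in range(6):
        cols[f"b2_{i}"] = f2 + 0.5 * r.standard_normal(n)
    u1, u2 = r.standard_normal(n), r.standard_normal(n)
    cols["noise_0"] = 0.55 * u1 + r.standard_normal(n)
    cols["noise_1"] = 0.55 * u1 + r.standard_normal(n)
    cols["noise_2"] = 0.3 * u2 + r.standard_normal(n)
    cols["noise_3"] = 0.3 * u2 + r.standard_normal(n)
    return ai.standardize(pd.DataFrame(cols))
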