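"""Shared fixtures: toy and full-size key pairs, and the synthetic study panel.

Key pairs are generated once per session with seeded RNGs so every test run
is reproducible; the 3072-bit pair and the trained study model are expensive
(tens of seconds) and shared across the acceptance tests.
"""

from random import Random

import numpy as np
import pytest

import cryptimpute as ci
from cryptimpute import paillier as pa


@pytest.fixture(scope="session")
def toy_kp():
    """The p=5, q=7 toy key (N=35, g=36): exhaustively checkable."""
    return pa.keypair_from_primes(5, 7, insecure_toy_mode=True,
                                  zero_cache_size=4, rng=Random(0))


@pytest.fixture(scope="session")
def kp64():
    """64-bit toy key: big enough for collision statistics, still fast."""
    return pa.keygen(64, rng=Random(3), insecure_toy_mode=True, zero_cache_size=16)


@pytest.fixture(scope="session")
def kp256():
    """256-bit toy key used by the encrypted-inference unit tests."""
    return pa.keygen(256, rng=Random(4), insecure_toy_mode=True, zero_cache_size=16)


@pytest.fixture(scope="session")
def kp1024():
    return pa.keygen(1024, rng=Random(5), zero_cache_size=32)


@pytest.fixture(scope="session")
def kp3072():
    return pa.keygen(3072, rng=Random(11), zero_cache_size=64)


@pytest.fixture(scope="session")
def study():
    """The synthetic study: 2000 individuals (1500 train / 500 test),
    13 blocks x 10 SNPs, 52 targets, k=10, scale=8 — trained once."""
    panel = ci.simulate_panel(ci.SimConfig(seed=7))
    train, test = panel.split(1500)
    model = ci.train_imputation_model(train, ci.ModelConfig())
    truth = np.column_stack([test.column(t) for t in model.target_ids])
    return {"panel": panel, "train": train, "test": test, "model": model,
            "truth": truth}
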