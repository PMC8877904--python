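import dataclasses

import numpy as np
import pytest

import broachtap as bt


@pytest.fixture(scope="session")
def small_fixated():
    """A short fixated-condition run shared across tests (12 blows)."""
    cfg = bt.preset("fixated_large", seed=7, n_blows=12)
    rec, depth_table, truth = bt.simulate_experiment(cfg)
    return cfg, rec, depth_table, truth


@pytest.fixture(scope="session")
def noiseless_fixated():
    """A short deterministic run: no noise floor, no energy scatter."""
    base = bt.preset("fixated_large", seed=0, n_blows=10)
    bands = tuple(dataclasses.replace(b, scatter_sigma_ln=0.0) for b in base.bands)
    cfg = dataclasses.replace(base, bands=bands, noise_floor=0.0)
    rec, depth_table, truth = bt.simulate_experiment(cfg)
    return cfg, rec, depth_table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
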