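import numpy as np
import pandas as pd
import pytest

import neoblastsig as nb


@pytest.fixture(scope="session")
def small_config():
    return nb.SimulationConfig(n_clusters=1500, n_transcripts=400, seed=101)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return nb.simulate_dataset(small_config)


def nb_counts(rng, mu, phi, shape):
    """Gamma-Poisson NB draws with var = mu + phi mu^2 (test-local oracle sampler)."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), shape)
    if phi < 1e-12:
        return rng.poisson(mu)
    return rng.poisson(rng.gamma(1.0 / phi, mu * phi))


@pytest.fixture
def null_counts_6():
    """2,000 null NB clusters, 3 vs 3, phi = 0.1, lognormal means."""
    rng = np.random.default_rng(77)
    n = 2000
    mu = np.exp(rng.normal(np.log(100), 0.6, n))
    counts = nb_counts(rng, mu[:, None], 0.1, (n, 6))
    return pd.DataFrame(counts, index=[f"g{i:04d}" for i in range(n)], columns=list("abcdef"))
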