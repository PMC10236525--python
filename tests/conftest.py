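import numpy as np
import pytest

from crtsace import CRTDataset, SimConfig, StrataParams, generate_crt

# Reference study conditions used across the suite: the membership and
# outcome coefficients of the synthetic-CRT default configuration.
BETA = np.array([-1.0, 0.3, 0.5])
GAMMA = np.array([-0.8, 0.6, 0.4])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_strata_params():
    return StrataParams(BETA, GAMMA)


@pytest.fixture(scope="session")
def small_crt():
    """A modest synthetic CRT (20 clusters x 8) with its truth."""
    cfg = SimConfig(m=8, n=20, seed=7)
    return generate_crt(cfg)


def make_dataset(
    n_clusters=4,
    size=5,
    p=2,
    treated=None,
    seed=0,
    all_survive=True,
):
    """Hand-rolled small dataset builder for unit tests."""
    rng = np.random.default_rng(seed)
    n = n_clusters * size
    cluster = np.repeat(np.arange(n_clusters), size)
    if treated is None:
        treated = np.arange(n_clusters) % 2
    D = np.asarray(treated)[cluster]
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    S = np.ones(n, dtype=int)
    Y = rng.normal(size=n)
    if not all_survive:
        S[rng.random(n) < 0.3] = 0
        Y = np.where(S == 1, Y, np.nan)
    return CRTDataset(cluster=cluster, D=D, S=S, Y=Y, X=X)
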