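import numpy as np
import pytest

from timescales import GeneratorSpec, ParcellationScheme, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230)


@pytest.fixture(scope="session")
def small_scheme():
    """A reduced two-network parcellation for cheap end-to-end tests."""

    networks = np.array(["alpha"] * 12 + ["beta"] * 8, dtype=object)
    return ParcellationScheme(parcel_ids=np.arange(1, 21), network_of=networks)


@pytest.fixture(scope="session")
def small_dataset(small_scheme):
    """A small three-state synthetic dataset (6 subjects, 20 parcels)."""

    spec = GeneratorSpec(n_subjects=6, parcellation=small_scheme, seed=7)
    return generate_dataset(spec)


def acf_double_loop(x, max_lag):
    """Literal double-loop biased autocorrelation estimator (test oracle).

    Computes the lag-m autocovariance (1/N) * sum_{t=1}^{N-m}
    (x_t - xbar)(x_{t+m} - xbar) divided by the biased variance, exactly as
    the defining sums read, in O(N * M) time.
    """

    x = np.asarray(x, dtype=float)
    n = x.size
    xbar = x.mean()
    var = sum((x[t] - xbar) ** 2 for t in range(n)) / n
    r = np.empty(max_lag + 1)
    for m in range(max_lag + 1):
        acov = 0.0
        for t in range(n - m):
            acov += (x[t] - xbar) * (x[t + m] - xbar)
        r[m] = (acov / n) / var
    return r
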