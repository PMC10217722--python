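import numpy as np
import pytest

from rpcca.simulation import simulate_linear_quadratic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230713)


@pytest.fixture(scope="session")
def benchmark_data():
    """One clean draw of the 8x3 linear-plus-quadratic benchmark design."""
    return simulate_linear_quadratic(100, 0.0, seed=42)


@pytest.fixture(scope="session")
def normal_scores():
    """Bivariate normal scores with rho = 0.8, n = 2000."""
    rho = 0.8
    gen = np.random.default_rng(7)
    z = gen.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=2000)
    return z[:, 0], z[:, 1], rho
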