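import numpy as np
import pytest

from hdassoc.simulate import SimulationConfig, simulate_dataset


def ols_oracle(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Independent per-pair least-squares fit: beta, se, t of the last column.

    Straight textbook OLS via lstsq + explicit (X'X)^-1 — shares no code
    with the block solver under test.
    """
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    return float(beta[-1]), float(se), float(beta[-1] / se)


@pytest.fixture(scope="session")
def small_dataset():
    """50 samples x 20 variants x 10 phenotypes, two planted effects."""
    cfg = SimulationConfig(n_i=50, n_t=20, n_p=10, seed=1,
                           effects=((2, 3, 0.7), (5, 0, -0.4)))
    return cfg, simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
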