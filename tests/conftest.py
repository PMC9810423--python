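import numpy as np
import pytest
from scipy.stats import poisson

import growthctl as g


def skellam_oracle(mu1: float, mu2: float, k: int) -> float:
    """Independent oracle: truncated double-sum convolution of two
    Poisson pmfs, P(X - Y = k) = sum_j P(X = j) P(Y = j - k), with the
    truncation chosen so the discarded tail is far below 1e-14."""
    cap = int(max(mu1, mu2) + 20 * np.sqrt(max(mu1, mu2) + 1) + 80)
    j = np.arange(max(0, k), cap)
    return float(np.sum(poisson.pmf(j, mu1) * poisson.pmf(j - k, mu2)))


def skellam_oracle_lower_tail(mu1: float, mu2: float, k_max: int) -> float:
    """Oracle for P(increment <= k_max)."""
    lo = -int(max(mu1, mu2) + 20 * np.sqrt(max(mu1, mu2) + 1) + 80)
    return float(sum(skellam_oracle(mu1, mu2, k) for k in range(lo, k_max + 1)))


@pytest.fixture(scope="session")
def tiny_config():
    return g.make_fixture("tiny")  # K=10, T=15


@pytest.fixture(scope="session")
def small_config():
    return g.make_fixture("small")  # K=50, T=60


@pytest.fixture(scope="session")
def paper_config():
    return g.default_config()  # K=500, l=1.5, T=750, N_initial=10


@pytest.fixture(scope="session")
def map_T150(paper_config):
    return g.solve_bellman(paper_config.replace(T=150))


@pytest.fixture(scope="session")
def map_T300(paper_config):
    return g.solve_bellman(paper_config.replace(T=300))


@pytest.fixture(scope="session")
def map_T750(paper_config):
    return g.solve_bellman(paper_config)


@pytest.fixture(scope="session")
def tensor500(paper_config):
    """Anticipative control tensor at full scale (K=500, cycle T=300).

    This is the single most expensive solved object in the suite (a
    Bellman solve per competitor size); shared across competition tests.
    """
    return g.build_anticipative_tensor(paper_config.replace(T=300))
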