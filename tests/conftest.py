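import numpy as np
import pytest

from bayesobs.config import TaskConfig
from bayesobs.gmm import GaussianMixture1D
from bayesobs.task import prior_set


@pytest.fixture(scope="session")
def cfg():
    return TaskConfig()


@pytest.fixture(scope="session")
def loss(cfg):
    return cfg.loss


@pytest.fixture(scope="session")
def gaussian_priors(cfg):
    return prior_set("gaussian", cfg)


@pytest.fixture(scope="session")
def bimodal_priors(cfg):
    return prior_set("bimodal", cfg)


@pytest.fixture(scope="session")
def unimodal_priors(cfg):
    # entropy-maximizing construction is expensive; built once per session
    return prior_set("unimodal", cfg)


def random_mixture(rng: np.random.Generator, max_components: int = 3) -> GaussianMixture1D:
    """A random, well-conditioned mixture for oracle comparisons."""
    k = int(rng.integers(1, max_components + 1))
    w = rng.dirichlet(np.ones(k) * 2.0)
    mu = rng.uniform(-0.3, 0.3, size=k)
    sd = rng.uniform(0.02, 0.15, size=k)
    return GaussianMixture1D(w, mu, sd)


@pytest.fixture
def rng():
    return np.random.default_rng(20240619)
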