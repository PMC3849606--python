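import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pathmi as pm

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expr(rng):
    """5 genes x 40 samples with a chain dependence G1->...->G5."""
    cfg = pm.SimulationConfig(n_genes=5, topology="chain", n_samples=40, seed=7)
    net = pm.generate_network(cfg)
    return pm.simulate_expression(net, cfg)


@pytest.fixture
def random_probability_matrix():
    """Factory: symmetric matrix of edge probabilities in (0, 1]."""
    def make(n, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(0.05, 1.0, size=(n, n))
        p = (p + p.T) / 2
        genes = tuple(chr(ord("a") + i) for i in range(n))
        return pm.DirectnessResult(
            pm.SymmetricGeneMatrix(genes, p), n_boot=100, smoothing="laplace")
    return make
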