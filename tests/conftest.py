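import numpy as np
import pytest

from akgp import MarkerMatrix, SimulationSpec, make_benchmark_fixture, simulate_phenotypes
from akgp.brr_engine import ChainSettings
from akgp.synthetic_data import simulate_markers


@pytest.fixture(scope="session")
def tiny_dataset():
    """30 shared lines x 2 environments x 20 markers."""
    return make_benchmark_fixture("tiny", seed=101)


@pytest.fixture(scope="session")
def single_env_dataset():
    """One environment, moderate signal: unit-test workhorse."""
    spec = SimulationSpec(n_per_env=[120], p=80, sigma2_g=0.6,
                          sigma2_eps=0.4, mu=1.0, seed=202)
    return simulate_phenotypes(simulate_markers(spec), spec)


@pytest.fixture
def short_chain():
    return ChainSettings(n_iter=1500, burn_in=300, thin=2, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_markers(rng, n, p, ids=None):
    """Helper: random biallelic dosage panel as a MarkerMatrix."""
    q = rng.uniform(0.1, 0.9, size=p)
    V = rng.binomial(2, q[None, :].repeat(n, axis=0)).astype(float)
    line_ids = ids if ids is not None else [f"L{i}" for i in range(n)]
    return MarkerMatrix(line_ids, [f"M{j}" for j in range(p)], V)
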