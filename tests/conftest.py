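import numpy as np
import pytest

from tolnet.simulate import SimulationConfig, simulate_timecourse, generate_priors


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down time course for fast unit tests."""
    return SimulationConfig(
        n_genes=40,
        n_proteins=30,
        n_clinical=3,
        n_true_edges=40,
        decoy_prior_edges=10,
        n_de_unique={"initiation": 4, "progression": 4, "tolerance": 5},
        n_de_shared=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, truth = simulate_timecourse(small_config)
    priors = generate_priors(small_config, truth)
    return dataset, truth, priors
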