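import numpy as np
import pytest

from standlab.synthetic import SimConfig, default_experiment_config, generate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """The standard 36-plot, 3-census synthetic experiment, seed 1."""
    return generate_experiment(default_experiment_config(seed=1))


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced experiment (2 treatments x 2 reps) for fast smoke tests."""
    cfg = SimConfig(seed=3, n_treatments=2, reps_per_treatment=2,
                    removal_levels=(0.0, 0.5))
    return generate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
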