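import numpy as np
import pytest

from fermaug.preprocess import (
    apply_normalizer,
    fit_normalizer,
    impute_missing_channel,
    to_vae_tensor,
)
from fermaug.simulate import SimulatorParams, simulate_study


@pytest.fixture(scope="session")
def default_params():
    return SimulatorParams()


@pytest.fixture(scope="session")
def noise_free_params():
    p = SimulatorParams()
    p.noise_sd = {k: 0.0 for k in p.noise_sd}
    p.between_experiment_cv = 0.0
    return p


@pytest.fixture(scope="session")
def study11(default_params):
    """The default simulated study: 11 cycles, 500 points, 2 sensor faults."""
    return simulate_study(default_params, n_experiments=11, seed=42)


@pytest.fixture(scope="session")
def imputed11(study11):
    return impute_missing_channel(study11, k=5)


@pytest.fixture(scope="session")
def normalizer11(imputed11):
    return fit_normalizer(imputed11, "minmax")


@pytest.fixture(scope="session")
def tensor11(imputed11, normalizer11):
    return to_vae_tensor(apply_normalizer(imputed11, normalizer11))


@pytest.fixture(scope="session")
def small_study():
    """A fast 5-cycle study on a 40-point grid (for plumbing tests)."""
    params = SimulatorParams(n_points=40, n_substeps=20)
    return simulate_study(params, n_experiments=5, fault_plan=[], seed=7)


@pytest.fixture(scope="session")
def small_imputed(small_study):
    return impute_missing_channel(small_study, k=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
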