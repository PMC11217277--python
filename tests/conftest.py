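import numpy as np
import pytest

from pennrheo import DatasetSpec, QuemadaParams, generate_dataset, get_preset


@pytest.fixture(scope="session")
def case1_params() -> QuemadaParams:
    """Default dispersion: C=2, S0=1, S_inf=0, eta_f=1e-3, phi_m=0.64, a=0.5um."""
    return get_preset("case1")


@pytest.fixture(scope="session")
def small_case1_dataset(case1_params):
    """Tiny case-1 grid (3 phi levels x 20 rates) for fast training tests."""
    return generate_dataset(
        DatasetSpec(case="case1", n_phi=3, N_shear=20, params=case1_params, seed=5)
    )


@pytest.fixture(scope="session")
def case1_dataset(case1_params):
    """The reference case-1 grid: n=3 phi levels, N=300 rates."""
    return generate_dataset(
        DatasetSpec(case="case1", n_phi=3, N_shear=300, params=case1_params, seed=5)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
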