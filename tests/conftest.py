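import numpy as np
import pytest

from anmbr import (
    BioParams,
    BioState,
    CleaningParams,
    ControlParams,
    FoulingState,
    MembraneParams,
    ModelParams,
    control_experiment_config,
    pilot_membrane_params,
)


@pytest.fixture(scope="session")
def pilot_membrane() -> MembraneParams:
    return pilot_membrane_params()


@pytest.fixture(scope="session")
def control_setup():
    """Operating point used for the control-strategy studies."""
    return control_experiment_config()


@pytest.fixture(scope="session")
def fast_solver() -> dict:
    """Looser solver settings for tests that only need qualitative output."""
    return dict(rtol=1e-6, atol=1e-9, n_eval=200)


@pytest.fixture(scope="session")
def simple_membrane() -> MembraneParams:
    """Round-number membrane constants for hand-arithmetic checks."""
    return MembraneParams(
        A0=1.0,
        epsilon=0.7,
        sigma=10.0,
        sigma_prime=10.0,
        alpha=1.0e11,
        alpha_prime=1.0e11,
        R0=1.0e13,
        delta_P=1.5e5,
        mu_visc=1.0e-3,
        Cs=0.1,
        Cx=0.1,
        Csmp=0.1,
        beta1=0.3,
        beta2=0.02,
    )


@pytest.fixture
def small_bio_state() -> BioState:
    return BioState(X1=1.4, X2=0.6, S1=1.2, S2=0.5, SMP=0.3, V=50.0)
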