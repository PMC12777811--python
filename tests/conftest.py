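import numpy as np
import pytest

from lymphpk import (
    LymphFlowModel,
    NoiseModel,
    PKParameters,
    default_nanoemulsion_params,
    default_oil_solution_params,
)


@pytest.fixture
def oil_params():
    return default_oil_solution_params()


@pytest.fixture
def nano_params():
    return default_nanoemulsion_params()


@pytest.fixture
def one_cpt_params():
    """A one-compartment animal for closed-form comparisons."""
    return PKParameters(
        fa=0.4, phi_lymph=0.1, eh=0.6, ka=0.7, klt=0.9, cl=30.0, vc=50.0
    )


@pytest.fixture
def exact_flow():
    """Deterministic lymph flow (no between-interval variation)."""
    return LymphFlowModel(mean_flow=70.0, cv_flow=0.0)


@pytest.fixture
def no_noise():
    return NoiseModel(residual_cv=0.0, iiv_cv=0.0, lloq=1.0)
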