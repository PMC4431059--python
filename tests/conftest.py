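import numpy as np
import pytest

from amdcea import load_parameters

#: flat tables for structural tests
ZERO_MORTALITY = {55: 0.0, 110: 0.0}
CERTAIN_DEATH = {55: 1.0, 110: 1.0}


@pytest.fixture(scope="session")
def base_params():
    return load_parameters()


@pytest.fixture
def zero_mortality_params(base_params):
    return base_params.with_overrides(
        mortality_male=ZERO_MORTALITY, mortality_female=ZERO_MORTALITY
    )


@pytest.fixture
def identity_matrices_params(zero_mortality_params):
    """Best band is absorbing: loading and monthly transitions are identity."""
    from amdcea import TransitionMatrix

    return zero_mortality_params.with_overrides(
        loading_row=np.array([1.0, 0, 0, 0, 0]),
        monthly=TransitionMatrix("monthly", np.eye(5)),
    )
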