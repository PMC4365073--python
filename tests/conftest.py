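import numpy as np
import pytest

from nbdiag.nb_fit import DesignSpec


@pytest.fixture
def study_design():
    """The log-linear study design: intercept + covariate 4..8, n = 100."""
    x = np.linspace(4.0, 8.0, 100)
    return DesignSpec(np.column_stack([np.ones(100), x]))


@pytest.fixture
def study_mu(study_design):
    return np.exp(study_design.X @ np.array([15.0, -1.5]))


@pytest.fixture
def rng():
    return np.random.default_rng(20250927)
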