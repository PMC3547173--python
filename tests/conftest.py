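import numpy as np
import pytest

from cmcfield.params import (FieldParameters, MicrocircuitParameters,
                             ObservationModel, default_parameters)


@pytest.fixture(scope="session")
def priors():
    """Default (prior-mean) parameter triple."""
    return default_parameters()


@pytest.fixture(scope="session")
def stable_circuit():
    """A weakly coupled, linearly stable microcircuit for time-domain oracles.

    The default operating point has exponentially growing linear modes (its
    spectrum is defined through the transfer function only), so simulation
    oracles use this low-gain variant, verified stable in the tests.
    """
    a = {(1, 1): 2.0, (1, 2): 20.0, (1, 4): 10.0,
         (2, 1): 20.0, (2, 2): 2.0, (2, 3): 10.0,
         (3, 2): 15.0, (3, 3): 2.0,
         (4, 1): 15.0, (4, 4): 2.0}
    params = MicrocircuitParameters(r=0.004, a=a)
    return params, FieldParameters(), ObservationModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
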