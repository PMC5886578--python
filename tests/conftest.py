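import warnings

import numpy as np
import pytest

import mechcell as mc


@pytest.fixture(scope="session")
def fitted():
    """Initialized MCF10A-style model from the noiseless omics fixture.

    Session-scoped: the average-cell initialization is the expensive step
    shared by the signaling, fate and population tests.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = mc.default_model()
        return model.fit(probe=False)


@pytest.fixture(scope="session")
def system(fitted):
    return fitted.system


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
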