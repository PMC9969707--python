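import numpy as np
import pytest

from cardioshape.phantom import PhantomParams, make_phantom


@pytest.fixture(scope="session")
def default_truth():
    """One default phantom with ED/ES frames rendered."""
    return make_phantom(PhantomParams(seed=3), frames="edes")


@pytest.fixture(scope="session")
def oracle_models(default_truth):
    """Oracle-guided template fit of the default phantom (ED, ES)."""
    from cardioshape.oracle import oracle_fit
    return oracle_fit(default_truth)


@pytest.fixture(scope="session")
def template():
    from cardioshape.meshfit import default_template
    return default_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
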