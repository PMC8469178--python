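import numpy as np
import pytest

import pvit


@pytest.fixture(scope="session")
def exp1():
    """Exponential baseline with unit rate."""
    return pvit.make_exponential_baseline(1.0)


@pytest.fixture(scope="session")
def example2_model():
    """Fixed-growth model whose survival is (1+t)^-3: rate 3, xi 3/2."""
    return pvit.ConditionalPVIT(pvit.make_exponential_baseline(3.0), 1.5)


@pytest.fixture(scope="session")
def example1_mixture():
    """Unit-Pareto growth g(xi)=1/xi^2 on [1,inf) over exponential(1/3)."""
    return pvit.MixtureModel(
        pvit.make_exponential_baseline(1.0 / 3.0), pvit.pareto_unit_frailty()
    )


@pytest.fixture(scope="session")
def uniform_mixture(exp1):
    """Uniform[1,2] growth over an exponential(1) baseline."""
    return pvit.MixtureModel(exp1, pvit.uniform_frailty(1.0, 2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
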