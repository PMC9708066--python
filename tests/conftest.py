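import numpy as np
import pytest

from thermotraits.tpc_fitting import SSParameters


def random_ss_params(rng: np.random.Generator) -> SSParameters:
    """A random valid Sharpe-Schoolfield parameter set covering the
    biologically plausible range."""
    e = rng.uniform(0.3, 1.5)
    return SSParameters(
        b0=10.0 ** rng.uniform(-2, 0),
        e=e,
        ed=e + rng.uniform(0.5, 5.0),
        tpk=rng.uniform(283.15, 323.15),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
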