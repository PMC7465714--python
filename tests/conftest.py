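import numpy as np
import pytest

import kimchikinetics as kk


@pytest.fixture(scope="session")
def ref() -> kk.KineticParameters:
    """The published reference constants (0-20 degC calibration)."""
    return kk.reference_parameters()


def random_parameters(rng: np.random.Generator) -> kk.KineticParameters:
    """A random but physically admissible parameter set for property tests."""
    return kk.KineticParameters(
        a0=rng.uniform(0.01, 0.5),
        a1=rng.uniform(0.0, 0.05),
        a2=rng.uniform(0.0, 0.005),
        q0=10.0 ** rng.uniform(-8, -2),
        nmax_intercept=rng.uniform(0.5, 1.5),
        nmax_slope=rng.uniform(0.0, 0.05),
    )
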