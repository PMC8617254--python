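import numpy as np
import pytest

from volscale import GlobalParams, make_genome
from volscale.genome import calibrate


@pytest.fixture(scope="session")
def gl():
    return GlobalParams()


@pytest.fixture(scope="session")
def small_homog(gl):
    """A 30-gene homogeneous genome plus its calibration."""
    genome = make_genome(30, K_cv=0.0, lifetime_cv=0.0, seed=11)
    return calibrate(genome, gl)


@pytest.fixture(scope="session")
def small_lognormal(gl):
    """A 200-gene lognormal genome (K CV 0.5, lifetime CV 1)."""
    genome = make_genome(200, K_cv=0.5, lifetime_cv=1.0, seed=12)
    return calibrate(genome, gl)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
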