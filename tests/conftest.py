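import numpy as np
import pytest
from hypothesis import settings

import girsanov as g

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")

DATA_DIR = __file__.rsplit("/", 1)[0] + "/data"


@pytest.fixture(scope="session")
def mb_potential():
    return g.MuellerBrown()


@pytest.fixture(scope="session")
def mb_biased_pair(mb_potential):
    return g.make_pair(mb_potential, g.make_bias(g.BiasSpec("linear", 1.0), 2),
                       as_bias=True)


@pytest.fixture(scope="session")
def params_2d():
    return g.LangevinParams(dt=0.0005, xi=5.0, T=300.0, masses=np.ones(2))


@pytest.fixture(scope="session")
def params_1d():
    return g.LangevinParams(dt=0.0005, xi=5.0, T=300.0, masses=np.ones(1))


@pytest.fixture(scope="session")
def mb_study():
    """Desk-scale paired biased/unbiased Mueller-Brown study (shared by the
    acceptance-level checks; ~25 s)."""
    return g.run_mb_experiment(g.mueller_brown_config(seed=11))


@pytest.fixture(scope="session")
def dw_study():
    """Double-well surrogate study with a 5 kJ/mol/nm linear bias."""
    return g.run_doublewell_surrogate(g.double_well_config(seed=5))
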