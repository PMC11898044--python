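import numpy as np
import pytest

from slbind.superlearner import default_learner_specs
from slbind.synthetic import SyntheticTableSpec, make_table

# Ensemble sizes for simulation-study and smoke-test registries. The
# production default (1000 trees) is exercised by the registry unit tests
# and the acceptance script; simulations use the same ten learners with
# smaller ensembles (see docs/methods.md).
SIM_TREES = 100
TINY_TREES = 30


@pytest.fixture(scope="session")
def linear_table():
    """Small linear synthetic table shared by fast tests."""
    return make_table(SyntheticTableSpec(n=60, seed=11))


@pytest.fixture(scope="session")
def tiny_specs():
    return default_learner_specs(seed=0, tree_estimators=TINY_TREES)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
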