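import warnings

import pytest

from minmicrobiome import (
    FunctionalitySpec,
    Params,
    build_targets,
    joint_fba,
    member_growths,
    scfa_fva_max,
)
from minmicrobiome import synthetic


def run_steps12(comm, spec, params):
    """Steps 1-2 on a prepared community: returns (theta_k, scfa_max, targets)."""
    res = joint_fba(comm)
    theta = member_growths(comm, res)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # toys lack some SCFA exchanges
        scfa_max, _ = scfa_fva_max(comm, spec, theta, params.gr_opt_frac)
    return theta, scfa_max, build_targets(theta, scfa_max, params)


@pytest.fixture
def toy3():
    return synthetic.toy_3()


@pytest.fixture
def toy5():
    return synthetic.toy_5_redundant()


@pytest.fixture
def toy9():
    return synthetic.toy_9_demo()


@pytest.fixture
def butyrate_spec():
    return FunctionalitySpec(constraint_id=3)


@pytest.fixture
def default_params():
    return Params()
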