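import numpy as np
import pytest

from multisyn.markov_structural import StructuralParams, pdel_profile
from multisyn.neuron_core import IOCurve, SystemPoint, activity_profile
from multisyn.rate_rules import RuleSpec

# published model configuration used as the reference working point
PAPER_STRUCTURAL = dict(ln_p_build=-16.0, rho=0.125, a=2.0, P=12)
PAPER_RULE = dict(kind="bcm_scaling", mu=0.2, theta=0.08, kappa=9.0, v_tss=0.1)
PAPER_POINT = dict(v_j=0.656, v_i_S0=0.2975)

# parameter set used for the rule-condition table (feedforward v_j = 0.08)
FIG3_PARAMS = dict(theta=0.1, kappa=1.0, v_tss=0.05, w_min=0.04, w_max=0.95)
FIG3_VJ = 0.08


@pytest.fixture(scope="session")
def io():
    return IOCurve.logistic()


@pytest.fixture(scope="session")
def paper_rule():
    return RuleSpec(**PAPER_RULE)


@pytest.fixture(scope="session")
def paper_sp():
    return StructuralParams.from_log_build(**PAPER_STRUCTURAL)


@pytest.fixture(scope="session")
def working_point():
    return SystemPoint.from_baseline(**PAPER_POINT)


@pytest.fixture(scope="session")
def paper_profile(io, paper_rule, paper_sp, working_point):
    return activity_profile(paper_sp.P, working_point, paper_rule, io)


@pytest.fixture(scope="session")
def paper_pdel(paper_sp, paper_profile):
    return pdel_profile(paper_sp, paper_profile)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
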