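import numpy as np
import pytest

from tobramipd import AssayErrorModel, CovariateSet, default_prior
from tobramipd.priors import DiscretePrior


@pytest.fixture(scope="session")
def prior():
    """The synthetic default prior (small seed-fixed instance)."""
    return default_prior(2000, seed=0)


@pytest.fixture(scope="session")
def small_prior():
    return default_prior(128, seed=7)


@pytest.fixture
def adult():
    """A typical study patient: female, 32 y, 57.5 kg, CLCR ~ 113 mL/min."""
    from tobramipd.pk import creatinine_for_clcr

    scr = creatinine_for_clcr(112.7, age=32.4, sex="female", body_weight=57.5)
    return CovariateSet(age=32.4, sex="female", body_weight=57.5, serum_creatinine=scr)


@pytest.fixture
def err_model():
    return AssayErrorModel(c0=0.1, c1=0.04)


def two_point_prior(p1, p2, w1=0.5):
    """Helper: a two-support-point prior with given weights."""
    theta = np.array([p1, p2], dtype=float)
    weights = np.array([w1, 1.0 - w1])
    lo = theta.min(axis=0) * 0.5
    hi = theta.max(axis=0) * 2.0
    return DiscretePrior(theta, weights, np.column_stack([lo, hi]), label="two-point")
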