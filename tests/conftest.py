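import numpy as np
import pytest

from switchmap.sharp import (
    ThresholdOrder,
    decompose_regions,
    get_analysis,
)


@pytest.fixture(scope="session")
def analysis():
    """Symbolic sharp-switch analysis for the theta2 < theta1 ordering."""
    return get_analysis(ThresholdOrder.theta2_lt_theta1)


@pytest.fixture(scope="session")
def catalog():
    """Full region catalog for the theta2 < theta1 ordering."""
    return decompose_regions(ThresholdOrder.theta2_lt_theta1)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_params6(rng, n, lo=-4.0, hi=4.0):
    """Random positive parameter rows (mu, gamma, eta, kappa, pi, epsilon)
    with the physical constraint eta > kappa."""
    mu, gam, kap, dlt, pi_, eps = np.exp(rng.uniform(lo, hi, size=(6, n)))
    eta = kap + dlt
    return np.column_stack([mu, gam, eta, kap, pi_, eps])


def random_thresholds(rng, n, lo=-4.0, hi=4.0):
    t = np.exp(rng.uniform(lo, hi, size=(n, 2)))
    th_lo = t.min(axis=1)
    th_hi = t.max(axis=1)
    return th_lo, th_hi
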