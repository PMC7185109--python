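from dataclasses import replace

import numpy as np
import pytest

from splitlbi import simulate_cohort
from splitlbi.simulate import SMALL_CONFIG, null_config


@pytest.fixture(scope="session")
def small_cohort():
    """Support-recovery-scale cohort (P~300, 10 lesion voxels), seed 1."""
    return simulate_cohort(replace(SMALL_CONFIG, seed=1))


@pytest.fixture(scope="session")
def null_small_cohort():
    """Same conditions with all planted effects off, seed 7."""
    return simulate_cohort(replace(null_config(SMALL_CONFIG), seed=7))


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """Full-cohort fitted model on the small strong-signal cohort."""
    from splitlbi import SplitLBIModel

    ds, truth = small_cohort
    res = SplitLBIModel.from_cohort(ds).fit(seed=1)
    return ds, truth, res


def random_logistic_instance(rng, n=30, p=8):
    """Small random logistic problem with a consistent label draw."""
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    eta = X @ beta * 0.5
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    if y.min() == y.max():  # force both classes
        y[0] = 1 - y[0]
    return X, y
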