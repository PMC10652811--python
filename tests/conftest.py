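import logging

import numpy as np
import pytest

from cycletrial.assays import default_truth
from cycletrial.cellcycle import CellCycleParams


@pytest.fixture(autouse=True)
def _quiet_clamp_warnings():
    # the effective-dose clamp warning is expected in deep-synergy regions
    logging.getLogger("cycletrial.response").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    return CellCycleParams(m=2, lambda_alpha=2.0, lambda_beta=5.6, lambda_gamma=7.9)


@pytest.fixture
def minus_dox():
    return default_truth("sensitive_minusDOX")


@pytest.fixture
def plus_dox():
    return default_truth("sensitive_plusDOX")
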