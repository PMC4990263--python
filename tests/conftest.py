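import zlib

import numpy as np
import pytest

from crcsim.params import ModelParams, NaturalHistoryParams, default_params
from crcsim.natural_history import MAX_ADENOMAS, Cohort


@pytest.fixture
def params() -> ModelParams:
    return default_params()


@pytest.fixture
def nh_params(params) -> NaturalHistoryParams:
    return params.natural_history


@pytest.fixture
def rng(request) -> np.random.Generator:
    # Deterministic but independent stream per test: Monte-Carlo checks in
    # different tests must not share (and jointly fail on) one unlucky stream.
    token = zlib.crc32(request.node.nodeid.encode())
    return np.random.default_rng(np.random.SeedSequence([20260921, token]))


def make_cohort(nh_params, n=1, frailty=0.0, age=60) -> Cohort:
    """A disease-free cohort with fixed frailty (no random draw)."""
    return Cohort(
        age=age,
        sizes=np.zeros((n, MAX_ADENOMAS), dtype=np.int8),
        villous=np.zeros((n, MAX_ADENOMAS), dtype=bool),
        high_grade=np.zeros((n, MAX_ADENOMAS), dtype=bool),
        cancer=np.zeros(n, dtype=np.int8),
        alive=np.ones(n, dtype=bool),
        frailty=np.full(n, float(frailty)),
        diagnosed_crc=np.zeros(n, dtype=bool),
        crc_age=np.full(n, -1, dtype=np.int16),
        recur_fate=np.zeros(n, dtype=np.int8),
    )
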