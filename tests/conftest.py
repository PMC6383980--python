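import numpy as np
import pytest
from hypothesis import settings

import breut

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lottery_b():
    return breut.parse_lottery("40:0.8,0:0.2", label="B")


@pytest.fixture(scope="session")
def pair_30_vs_b(lottery_b):
    return breut.LotteryPair(breut.parse_lottery("30:1", label="A"), lottery_b, label="{A,B}")


@pytest.fixture(scope="session")
def core_035():
    return breut.CorePrefs(0.35, 1.0)


@pytest.fixture(scope="session")
def core_023():
    return breut.CorePrefs(0.23, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20259)
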