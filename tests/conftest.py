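import pytest

from twinbayes import TwinCounts

# Published count vectors used across the suite: two simulated datasets
# (independence: 100k+100k pairs at pi=1%, q=pi; familial clustering:
# 4k+6k pairs at pi=1%, q_mz=0.40, q_dz=0.10) and three real studies
# (Danish cleft lip; Danish and Finnish rheumatoid arthritis).


@pytest.fixture(scope="session")
def independence_counts():
    return TwinCounts(6, 1876, 98118), TwinCounts(12, 2007, 97981)


@pytest.fixture(scope="session")
def clustering_counts():
    return TwinCounts(12, 47, 3941), TwinCounts(4, 103, 5893)


@pytest.fixture(scope="session")
def cleft_lip_counts():
    return TwinCounts(3, 8, 4474), TwinCounts(1, 14, 8164)


@pytest.fixture(scope="session")
def ra_danish_counts():
    return TwinCounts(4, 58, 7517), TwinCounts(2, 126, 11666)


@pytest.fixture(scope="session")
def ra_finnish_counts():
    return TwinCounts(9, 64, 4064), TwinCounts(6, 167, 8983)
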