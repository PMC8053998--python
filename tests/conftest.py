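import numpy as np
import pytest

from sessile import AllometryParams, CompetitionParams


@pytest.fixture
def default_allometry() -> AllometryParams:
    return AllometryParams()


@pytest.fixture
def default_competition() -> CompetitionParams:
    return CompetitionParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
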