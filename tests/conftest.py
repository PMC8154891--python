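import numpy as np
import pytest

from peptex.cycle import PeptideAffinities
from peptex.synth import preset


@pytest.fixture(scope="session")
def tax9_wt() -> PeptideAffinities:
    return preset("TAX9", "WT")


@pytest.fixture(scope="session")
def tax9_loopless() -> PeptideAffinities:
    return preset("TAX9", "dG24R36")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20211026)
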