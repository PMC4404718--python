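import numpy as np
import pytest

from causalq.causal_models import ContingencyTable, Grid, PriorSpec
from causalq.synthetic import build_contingency, stimulus_tables


@pytest.fixture(scope="session")
def c3_generative() -> ContingencyTable:
    return build_contingency("C3", "generative")


@pytest.fixture(scope="session")
def all_tables():
    return stimulus_tables()


@pytest.fixture(scope="session")
def grid() -> Grid:
    return Grid(0.005)


@pytest.fixture(scope="session")
def fine_grid() -> Grid:
    return Grid(0.0025)


@pytest.fixture(scope="session")
def uniform_prior() -> PriorSpec:
    return PriorSpec("uniform")


@pytest.fixture(scope="session")
def ss_prior() -> PriorSpec:
    return PriorSpec("SS", alpha=5.0)
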