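import numpy as np
import pytest

from geotypekit import load_table1_fixture, load_table3_fixture


@pytest.fixture(scope="session")
def table1():
    """The packaged 41-strain allelic-profile table: (matrix, strains)."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def primers():
    return load_table3_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_921)
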