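import numpy as np
import pytest

from thermogerm import germination_data as gd


@pytest.fixture(scope="session")
def fixture_tables():
    """The five packaged cultivar assays, loaded once."""
    return {c: gd.builtin_table(c) for c in gd.CULTIVARS}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
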