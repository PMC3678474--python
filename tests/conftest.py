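import numpy as np
import pytest

from coralpd import parse_newick, simulate_yule


@pytest.fixture
def balanced4():
    """Balanced 4-tip unit tree: root age 2, total branch length 6."""
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar5():
    return parse_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")


@pytest.fixture
def balanced8():
    return parse_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")


@pytest.fixture
def caterpillar8():
    s = "(((((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5):1,G:6):1,H:7);"
    return parse_newick(s)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def yule200():
    """One 200-tip pure-birth tree, fixed seed (shared across tests)."""
    return simulate_yule(200, np.random.default_rng(77))
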