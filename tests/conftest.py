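import numpy as np
import pytest

from panne.treeutil import parse_newick


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")


@pytest.fixture
def six_leaf_tree():
    return parse_newick(
        "(((A:0.1,B:0.2):0.15,C:0.3):0.1,((D:0.25,E:0.05):0.2,F:0.4):0.12);"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
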