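import numpy as np
import pytest

from mkasr import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20120716)


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")


@pytest.fixture
def four_tip_tree():
    return parse_newick("((A:0.4,B:0.7):0.3,(C:0.2,D:1.1):0.5);")
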