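import numpy as np
import pytest

from thermodiv.simulate import simulate_bd_tree, simulate_bm_trait, simulate_mk_binary
from thermodiv.trees import parse_newick


@pytest.fixture(scope="session")
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_tip():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule100():
    """A 100-tip pure-birth tree reused across statistical tests."""
    tree, _ = simulate_bd_tree(0.3, 0.0, ("n_tips", 100), seed=1234)
    return tree


@pytest.fixture(scope="session")
def bd50():
    """A 50-tip birth-death tree."""
    tree, _ = simulate_bd_tree(0.3, 0.1, ("n_tips", 50), seed=77)
    return tree
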