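import numpy as np
import pytest

from phylofabric.trees import read_newick


@pytest.fixture
def tree3():
    """((A:1,B:1):1,C:2); -- the 3-tip worked example."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star2():
    """2-tip star with unit branches."""
    return read_newick("(A:1,B:1);")


@pytest.fixture
def polytomy3():
    return read_newick("(A:1,B:1,C:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
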