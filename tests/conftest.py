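import numpy as np
import pytest

import cladediv as cd


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2); — the worked covariance/stem-age example."""
    return cd.TimeTree.from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def six_tip():
    """Six-tip tree with two obvious herbivory sister pairs."""
    return cd.TimeTree.from_string("(((A:1,B:1):1,(C:1,D:1):1):1,(E:2,F:2):1);")


@pytest.fixture
def yule20():
    return cd.simulate_yule_tree(20, 100.0, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20150924)
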