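import numpy as np
import pytest

from caratlas.graph import build_graph
from caratlas.synthetic import make_lattice


@pytest.fixture
def path_graph():
    """Three areas in a line: A - B - C."""
    return build_graph([("A", "B"), ("B", "C")], ["A", "B", "C"])


@pytest.fixture
def lattice44():
    return make_lattice(4, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
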