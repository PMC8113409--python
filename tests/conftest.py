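import logging

import numpy as np
import pytest

from gdvnet.catalog import build_catalog
from gdvnet.graph import SimpleGraph

# the GCM constant-column warning is expected on sparse synthetic cohorts
logging.getLogger("gdvnet.comparison").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


def random_graph(rng: np.random.Generator, n: int, p: float) -> SimpleGraph:
    a = rng.random((n, n)) < p
    return SimpleGraph(n, [(i, j) for i in range(n) for j in range(i + 1, n)
                           if a[i, j]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# canonical small graphs used across modules
@pytest.fixture
def triangle():
    return SimpleGraph(3, [(0, 1), (0, 2), (1, 2)])


@pytest.fixture
def path3():
    return SimpleGraph(3, [(0, 1), (1, 2)])
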