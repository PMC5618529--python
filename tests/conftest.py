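import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from netclust import Network


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def triangle():
    return Network([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def two_k4_bridge():
    """Two K4 cliques joined by a single bridge edge d–e."""
    edges = (
        [tuple(p) for p in itertools.combinations("abcd", 2)]
        + [tuple(p) for p in itertools.combinations("efgh", 2)]
        + [("d", "e")]
    )
    return Network(edges)


def k_complete(names):
    return Network([tuple(p) for p in itertools.combinations(names, 2)])
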