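import numpy as np
import pytest
from hypothesis import settings

from ffgcn.graph import MultichannelRecording, WeightedGraph

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def random_weighted_graph(rng: np.random.Generator, n: int,
                          density: float = 0.8) -> WeightedGraph:
    """Random symmetric adjacency with weights in (0, 1), zero diagonal."""
    a = rng.uniform(0.05, 0.95, size=(n, n))
    mask = rng.random((n, n)) < density
    a = np.triu(a * mask, k=1)
    a = a + a.T
    return WeightedGraph(a)


@pytest.fixture
def rng():
    return np.random.default_rng(20240328)


@pytest.fixture
def small_recording(rng):
    return MultichannelRecording(
        rng.standard_normal((3, 5)), ["a", "b", "c"], 100.0, label=0)
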