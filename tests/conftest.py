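import numpy as np
import pytest

from microcal.morphology import MorphTree, SwcNode


@pytest.fixture
def straight_process_tree() -> MorphTree:
    """Unbranched process along +x from the cell centre out to 23 µm."""
    nodes = [SwcNode(1, "soma", 0.0, 0.0, 0.0, 5.0, -1)]
    nodes += [SwcNode(i + 2, "process", float(i + 1), 0.0, 0.0, 0.5, i + 1)
              for i in range(23)]
    return MorphTree(nodes, center=(0.0, 0.0, 0.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
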