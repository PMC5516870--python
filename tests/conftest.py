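import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from lineagespec.priors import ACTIVATION, INHIBITION, SignedEdge
from lineagespec.synthetic import generate_system, write_system


def random_signed_network(rng: np.random.Generator, n: int, edge_prob: float = 0.3):
    """Random signed digraph (self-loops allowed) for dynamics tests."""
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for s in nodes:
        for t in nodes:
            if rng.random() < edge_prob:
                sign = ACTIVATION if rng.random() < 0.5 else INHIBITION
                edges.append(SignedEdge(source=s, target=t, sign=sign))
    return nodes, edges


@pytest.fixture(scope="session")
def planted_system():
    """One default planted tri-population system shared across tests."""
    return generate_system(seed=7)


@pytest.fixture(scope="session")
def planted_files(planted_system, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("system")
    return write_system(planted_system, outdir)
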