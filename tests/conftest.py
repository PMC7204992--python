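import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from rnscore.io import ExpressionDataset, PPINetwork


def make_network(edges, confidence=0.95) -> PPINetwork:
    """Build a PPINetwork from bare (u, v) pairs for topology tests."""
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, confidence=confidence)
    return PPINetwork(g)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes × 4 samples with one obvious DEG (gA up in tumor)."""
    values = pd.DataFrame(
        {
            "s1": [5.0, 2.0, 1.0],
            "s2": [5.1, 2.1, 1.1],
            "s3": [2.0, 2.0, 1.0],
            "s4": [2.1, 2.2, 1.2],
        },
        index=["gA", "gB", "gC"],
    )
    groups = pd.Series(
        ["tumor", "tumor", "normal", "normal"], index=values.columns, name="group"
    )
    return ExpressionDataset("tiny", values, groups)


@pytest.fixture
def path_graph() -> PPINetwork:
    return make_network([("A", "B"), ("B", "C")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
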