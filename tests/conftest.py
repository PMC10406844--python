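import networkx as nx
import numpy as np
import pandas as pd
import pytest

from micronet import AbundanceTable


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        [[1, 2, 3], [4, 5, 6]],
        index=["s1", "s2"],
        columns=["Flavobacteriaceae", "Alteromonadaceae", "Pseudomonadaceae"],
    )
    return AbundanceTable(counts)


@pytest.fixture
def grouped_table():
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.integers(0, 200, size=(12, 8)),
        index=[f"s{i}" for i in range(12)],
        columns=[f"F{j:03d}" for j in range(8)],
    )
    meta = pd.DataFrame(
        {"aggregation": ["A"] * 4 + ["B"] * 4 + ["C"] * 4},
        index=counts.index,
    )
    return AbundanceTable(counts, meta)


@pytest.fixture
def two_triangles():
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture
def bridged_triangles(two_triangles):
    g = two_triangles.copy()
    g.add_edge(2, 3)
    return g
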