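import networkx as nx
import numpy as np
import pandas as pd
import pytest

from wnnets import ComparisonDesign


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 12) -> nx.Graph:
    """Small random connected simple graph: random tree plus random extras."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    order = rng.permutation(n)
    for pos in range(1, n):
        g.add_edge(nodes[order[pos]], nodes[order[int(rng.integers(0, pos))]])
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            g.add_edge(nodes[i], nodes[j])
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def spc_file(tmp_path):
    path = tmp_path / "spc.tsv"
    path.write_text(
        "protein\ts1\ts2\n"
        "A\t10\t20\n"
        "B\t0\t3\n"
        "C\t4\t5\n"
    )
    return path


@pytest.fixture
def mw_file(tmp_path):
    path = tmp_path / "mw.tsv"
    path.write_text("protein\tweight\nA\t10\nB\t5\nC\t2\n")
    return path


@pytest.fixture
def path_graph():
    """Path a-b-c: the smallest master with distinct neighbourhoods."""
    return nx.Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def two_group_design():
    return ComparisonDesign(
        groups={
            "ctrl": ["c1", "c2", "c3", "c4", "c5", "c6"],
            "trt": ["t1", "t2", "t3", "t4", "t5", "t6"],
        },
        comparisons=(("trt", "ctrl"),),
    )
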