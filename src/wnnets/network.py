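"""Master-network construction, weighted-node expansion, and degree.

A *master network* is the shared, unweighted PPI graph.  For one sample, each
master node carries a strictly positive weight (its normalized spectral
count); the weighted-nodes network (WNNet) is obtained by adding ``w(v) - 1``
copies of each node v, fully interconnecting v with its copies, and wiring
every copy to everything v was wired to (masters and their copies alike).

Under this construction the degree of a master node v, counting neighbours
outside its own clique, is simply the sum of the weights of its master-network
neighbours:

    degree(v) = sum_{u ~ v} w(u)

That analytic form accepts real-valued weights directly and is the substrate
of all downstream statistics; the explicit expansion (:func:`materialize_wnnet`
and :func:`structural_degree`) exists to validate it and to export example
networks, since materializing is quadratic in the copy counts.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_master_network",
    "integerize_weights",
    "materialize_wnnet",
    "analytic_degree",
    "structural_degree",
    "degree_matrix",
]


def build_master_network(
    edges: pd.DataFrame,
    proteins: set[str] | list[str],
    score_threshold: float = 400.0,
    inclusive: bool = True,
) -> nx.Graph:
    """Build the master network from a cleaned edge table.

    Keeps edges whose confidence score passes ``score_threshold`` (``>=`` by
    default, matching STRING's medium-confidence semantics; set
    ``inclusive=False`` for a strict ``>``) and whose endpoints are both in
    ``proteins``, then returns the largest connected component of the induced
    simple graph.  Ties between equal-sized components are broken by the
    lexicographically smallest sorted node tuple, so the result is
    deterministic.

    The returned graph records provenance in ``graph.graph``:
    ``score_threshold``, ``component_sizes`` (all components, descending) and
    ``dropped_proteins`` (input proteins absent from the selected component).
    """
    proteins = set(map(str, proteins))
    if not proteins:
        raise ValueError("protein set is empty")
    score_ok = edges["score"] >= score_threshold if inclusive else edges["score"] > score_threshold
    keep = edges.loc[
        score_ok & edges["protein_a"].isin(proteins) & edges["protein_b"].isin(proteins)
    ]
    g = nx.Graph()
    g.add_edges_from(zip(keep["protein_a"], keep["protein_b"]))
    if g.number_of_edges() == 0:
        raise ValueError(
            "empty graph: no edge passes the score threshold within the protein set"
        )
    components = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), tuple(sorted(c))),
    )
    master: nx.Graph = g.subgraph(components[0]).copy()
    master.graph["score_threshold"] = float(score_threshold)
    master.graph["component_sizes"] = [len(c) for c in components]
    master.graph["dropped_proteins"] = sorted(proteins - set(master.nodes))
    return master


def integerize_weights(
    weights: pd.Series | Mapping[Hashable, float], decimals: int = 4
) -> tuple[pd.Series, float]:
    """Map positive real weights to natural numbers: ``max(1, round(w * 10^d))``.

    The expansion needs whole copy counts; scaling by ``10^decimals`` before
    rounding preserves ``decimals`` digits, and the floor at 1 guarantees a
    retained protein is never erased by rounding (any positive weight, however
    small, still contributes a node).  The mapping is monotone non-decreasing.
    Returns ``(integer_weights, scale_factor)`` with ``scale_factor = 10^decimals``.
    """
    w = pd.Series(weights, dtype=float)
    if (w <= 0).any():
        bad = w.index[w <= 0].tolist()
        raise ValueError(f"non-positive weights for {bad}; weights must be > 0")
    scale = float(10**decimals)
    ints = np.maximum(1, np.rint(w.to_numpy() * scale)).astype(int)
    return pd.Series(ints, index=w.index), scale


def materialize_wnnet(
    master: nx.Graph, weights: pd.Series | Mapping[Hashable, int]
) -> nx.Graph:
    """Explicitly expand a master network under integer node weights.

    Each master node v of weight w(v) is joined by copies ``v.1 .. v.(w-1)``;
    v and its copies form a clique, and for every master edge (u, v) all
    members of u's clique are wired to all members of v's clique.  Node
    attributes: ``is_copy``, ``origin`` (the master id) and ``weight`` (on
    masters).  The resulting graph has ``sum_v w(v)`` nodes and
    ``sum_{(u,v) in E} w(u) w(v) + sum_v C(w(v), 2)`` edges.
    """
    w = pd.Series(weights)
    missing = [v for v in master.nodes if v not in w.index]
    if missing:
        raise ValueError(f"no weight for master nodes {missing}")
    if (w.loc[list(master.nodes)] < 1).any():
        raise ValueError("integer weights must be >= 1")

    expanded = nx.Graph()
    cliques: dict[Hashable, list] = {}
    for v in master.nodes:
        wv = int(w[v])
        members = [v] + [f"{v}.{k}" for k in range(1, wv)]
        cliques[v] = members
        expanded.add_node(v, is_copy=False, origin=str(v), weight=wv)
        for k, copy in enumerate(members[1:], start=1):
            expanded.add_node(copy, is_copy=True, origin=str(v), copy_index=k)
        expanded.add_edges_from(combinations(members, 2))
    for u, v in master.edges:
        expanded.add_edges_from(product(cliques[u], cliques[v]))
    return expanded


def analytic_degree(
    master: nx.Graph, weights: pd.Series | Mapping[Hashable, float]
) -> pd.Series:
    """Degree of every master node: the sum of its neighbours' weights.

    Works directly on real-valued weights — no integerization or expansion is
    needed.  Note the value does not depend on the node's own weight; a
    protein's prominence in a WNNet is driven entirely by its neighbourhood.
    """
    w = pd.Series(weights, dtype=float)
    missing = [v for v in master.nodes if v not in w.index]
    if missing:
        raise ValueError(f"no weight for master nodes {missing}")
    if (w.loc[list(master.nodes)] <= 0).any():
        raise ValueError("weights must be > 0")
    return pd.Series(
        {v: float(sum(w[u] for u in master.neighbors(v))) for v in master.nodes},
        name="degree",
    )


def structural_degree(wnnet: nx.Graph) -> pd.Series:
    """Plain graph-theoretic degree of every node (masters and copies) in an
    expanded WNNet.  Serves as the independent oracle for the analytic degree:
    for a master node v, structural degree = analytic degree + (w(v) - 1)."""
    return pd.Series(dict(wnnet.degree()), name="structural_degree")


def degree_matrix(master: nx.Graph, weights: pd.DataFrame) -> pd.DataFrame:
    """Analytic degree of every master node in every sample.

    ``weights`` is a proteins x samples matrix covering at least the master
    nodes; column j of the result is ``analytic_degree`` under sample j's
    weights, computed in one sparse adjacency product.
    """
    nodes = list(master.nodes)
    missing = [v for v in nodes if v not in weights.index]
    if missing:
        raise ValueError(f"master nodes missing from the weight matrix: {missing}")
    sub = weights.loc[nodes]
    if (sub.to_numpy() <= 0).any():
        raise ValueError("weights must be > 0")
    adj = nx.to_scipy_sparse_array(master, nodelist=nodes, format="csr")
    values = adj @ sub.to_numpy(dtype=float)
    return pd.DataFrame(values, index=pd.Index(nodes, name="protein"), columns=sub.columns)
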