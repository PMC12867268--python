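"""PPI network post-processing: hub scoring and dense-module detection.

The analysis graph is built from a STRING-style weighted edge list by keeping
edges with combined score >= 0.4 (inclusive) and is simple, undirected and
unweighted thereafter. Hub scores: Degree; Maximal Clique Centrality
(MCC(v) = sum over maximal cliques C containing v of (|C|-1)!); Edge
Percolated Component (mean size of v's component, excluding v, under random
independent edge removal). Dense modules come from the MCODE procedure:
k-core-density vertex weighting, seeded complex growth, and a haircut pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io import EdgeList

__all__ = [
    "build_graph",
    "degree_scores",
    "mcc_scores",
    "epc_scores",
    "hub_table",
    "McodeModule",
    "mcode",
    "top_modules",
]

STRING_CUTOFF = 0.4


def build_graph(edges: EdgeList, cutoff: float = STRING_CUTOFF) -> nx.Graph:
    """Unweighted graph of edges with combined_score >= cutoff.

    Endpoints of sub-threshold edges are retained as isolated nodes.
    """
    g = nx.Graph()
    for a, b, s in edges.edges:
        g.add_node(a)
        g.add_node(b)
        if s >= cutoff:
            g.add_edge(a, b)
    return g


def degree_scores(graph: nx.Graph) -> dict[str, int]:
    return {v: int(d) for v, d in graph.degree()}


def mcc_scores(graph: nx.Graph) -> dict[str, int]:
    """Maximal clique centrality: sum of (|C| - 1)! over maximal cliques at v."""
    scores = {v: 0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    for v in graph.nodes:  # isolated nodes form a trivial maximal 1-clique
        if graph.degree(v) == 0:
            scores[v] = 0
    return scores


def epc_scores(
    graph: nx.Graph,
    retain_threshold: float = 0.5,
    n_iter: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Edge percolated component score by Monte Carlo.

    Each iteration removes every edge independently with probability
    ``retain_threshold``; EPC(v) is the mean count of *other* nodes left in
    v's connected component. Isolated nodes score exactly 0.
    """
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return {}
    edge_arr = np.array(
        [(index[a], index[b]) for a, b in graph.edges], dtype=np.int64
    ).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    totals = np.zeros(n)
    for _ in range(n_iter):
        keep = rng.random(edge_arr.shape[0]) >= retain_threshold
        rows = edge_arr[keep, 0]
        cols = edge_arr[keep, 1]
        adj = coo_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(n, n)
        )
        n_comp, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels, minlength=n_comp)
        totals += sizes[labels] - 1
    return {v: float(totals[index[v]] / n_iter) for v in nodes}


def hub_table(
    graph: nx.Graph,
    epc_iters: int = 1000,
    seed: int = 0,
) -> list[dict]:
    """All three hub scores per node with per-method ranks (1 = best)."""
    deg = degree_scores(graph)
    mcc = mcc_scores(graph)
    epc = epc_scores(graph, n_iter=epc_iters, seed=seed)
    nodes = sorted(graph.nodes)
    rows = []
    ranks: dict[str, dict[str, int]] = {}
    for method, score in (("degree", deg), ("mcc", mcc), ("epc", epc)):
        order = sorted(nodes, key=lambda v: (-score[v], v))
        for rank, v in enumerate(order, start=1):
            ranks.setdefault(v, {})[method] = rank
    for v in nodes:
        rows.append(
            {
                "node": v,
                "degree": deg[v],
                "mcc": mcc[v],
                "epc": epc[v],
                "rank_degree": ranks[v]["degree"],
                "rank_mcc": ranks[v]["mcc"],
                "rank_epc": ranks[v]["epc"],
            }
        )
    return rows


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------


@dataclass
class McodeModule:
    members: frozenset[str]
    seed_node: str
    score: float  # density × size
    rank: int


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def _vertex_weights(graph: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    """Stage 1: weight = k_max × density of the highest k-core of the closed
    neighborhood; vertices below the degree cutoff weigh 0."""
    weights: dict[str, float] = {}
    for v in graph.nodes:
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = graph.subgraph(list(graph.neighbors(v)) + [v])
        core_nums = nx.core_number(nbhd)
        k_max = max(core_nums.values())
        core = nbhd.subgraph([u for u, k in core_nums.items() if k >= k_max])
        weights[v] = k_max * _density(core)
    return weights


def mcode(
    graph: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    fluff: bool = False,
) -> list[McodeModule]:
    """MCODE dense-module detection.

    Complexes grow breadth-first from the highest-weighted unvisited seed,
    admitting neighbors whose vertex weight exceeds
    seed_weight × (1 − node_score_cutoff), to at most ``max_depth`` hops.
    The haircut pass iteratively strips degree-1 members; complexes lacking a
    ``k_core``-core are discarded. score = density × size; modules are sorted
    by score descending, ties by smallest lexicographic member.
    """
    weights = _vertex_weights(graph, degree_cutoff)
    visited: set[str] = set()
    raw_modules: list[tuple[set[str], str]] = []
    for seed_node in sorted(graph.nodes, key=lambda v: (-weights[v], v)):
        if seed_node in visited or weights[seed_node] <= 0.0:
            continue
        threshold = weights[seed_node] * (1.0 - node_score_cutoff)
        members = {seed_node}
        frontier = [seed_node]
        depth = 0
        while frontier and depth < max_depth:
            nxt: list[str] = []
            for u in frontier:
                for nb in sorted(graph.neighbors(u)):
                    if nb in members or nb in visited:
                        continue
                    if weights[nb] > threshold:
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
            depth += 1
        visited |= members
        raw_modules.append((members, seed_node))

    modules: list[McodeModule] = []
    for members, seed_node in raw_modules:
        sub = graph.subgraph(members).copy()
        if haircut:
            while True:
                leaves = [v for v in sub.nodes if sub.degree(v) <= 1]
                if not leaves or sub.number_of_nodes() <= len(leaves):
                    break
                sub.remove_nodes_from(leaves)
        if sub.number_of_nodes() < 2:
            continue
        core_nums = nx.core_number(sub)
        if max(core_nums.values()) < k_core:
            continue
        score = _density(sub) * sub.number_of_nodes()
        if score <= 0:
            continue
        modules.append(
            McodeModule(frozenset(sub.nodes), seed_node, score, rank=0)
        )
    modules.sort(key=lambda m: (-m.score, min(m.members)))
    for i, m in enumerate(modules, start=1):
        m.rank = i
    return modules


def top_modules(modules: Sequence[McodeModule], n: int = 5) -> list[McodeModule]:
    """The paper-style top-n modules by MCODE score."""
    return list(modules[:n])
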