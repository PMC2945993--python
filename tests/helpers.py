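"""Shared test utilities: graph builders and independent oracles."""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from gridwave.pathway_model import PathwayGraph, Reaction, build_pathway_graph


def graph_from_nx(g: nx.Graph, pathway_id: str = "T", genes: bool = True) -> PathwayGraph:
    """Realize a networkx topology as a reaction graph via synthetic metabolites."""
    subs: dict = {v: set() for v in g.nodes}
    prods: dict = {v: set() for v in g.nodes}
    for k, (u, v) in enumerate(g.edges):
        prods[u].add(f"M{k}")
        subs[v].add(f"M{k}")
    reactions = []
    for v in g.nodes:
        if not subs[v] and not prods[v]:
            subs[v] = {f"iso{v}"}
        reactions.append(
            Reaction(
                f"R{v}",
                frozenset(subs[v]),
                frozenset(prods[v]),
                frozenset({f"G{v}"}) if genes else frozenset(),
            )
        )
    return build_pathway_graph(pathway_id, reactions)


def connected_atlas_graphs(max_nodes: int = 6, min_nodes: int = 2) -> list[nx.Graph]:
    """All connected graphs up to isomorphism with min_nodes..max_nodes nodes."""
    return [
        g
        for g in nx.graph_atlas_g()[1:]
        if min_nodes <= g.number_of_nodes() <= max_nodes and nx.is_connected(g)
    ]


def exact_rank_sum_p(a, b) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Independent oracle: enumerates all C(n_a+n_b, n_a) ways of assigning the
    pooled ranks to group a and doubles the smaller tail of the U statistic.
    Assumes tie-free data.
    """
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n = len(pooled)
    na = len(a)
    rank = {v: r for r, v in enumerate(pooled, start=1)}
    u_obs = sum(rank[v] for v in a) - na * (na + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, n + 1), na):
        us.append(sum(combo) - na * (na + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


def min_total_edge_length_bruteforce(g: nx.Graph, side: int) -> int:
    """Exhaustive minimum total Manhattan edge length on a side x side grid."""
    nodes = list(g.nodes)
    cells = [(i, j) for i in range(side) for j in range(side)]
    edges = [(nodes.index(u), nodes.index(v)) for u, v in g.edges]
    best = math.inf
    for combo in itertools.permutations(cells, len(nodes)):
        obj = sum(
            abs(combo[x][0] - combo[y][0]) + abs(combo[x][1] - combo[y][1])
            for x, y in edges
        )
        best = min(best, obj)
    return int(best)
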