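"""Reaction-neighborhood graphs of metabolic pathways.

A pathway is modelled with enzymatic reactions as nodes; two reactions are
neighbors when some metabolite is the product of one and the substrate of
the other (or vice versa).  Metabolites themselves are not nodes — they only
induce the adjacency.  Pathways in which no reaction is connected to any
other carry no neighborhood signal and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "Reaction",
    "PathwayGraph",
    "build_pathway_graph",
    "merge_duplicate_reactions",
    "filter_pathways",
]


@dataclass(frozen=True)
class Reaction:
    """One enzymatic reaction with its gene/EC annotation.

    ``substrates`` and ``products`` hold metabolite identifiers; the union
    must be non-empty for the reaction to take part in a neighborhood.
    """

    reaction_id: str
    substrates: frozenset[str] = frozenset()
    products: frozenset[str] = frozenset()
    gene_ids: frozenset[str] = frozenset()
    ec_numbers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", frozenset(self.substrates))
        object.__setattr__(self, "products", frozenset(self.products))
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        object.__setattr__(self, "ec_numbers", frozenset(self.ec_numbers))


@dataclass
class PathwayGraph:
    """Reactions plus a symmetric, zero-diagonal binary adjacency matrix.

    Node order of ``adjacency`` follows ``reactions``.  ``merge_map`` records,
    after :func:`merge_duplicate_reactions`, which original reactions each
    node stands for (identity map for unmerged graphs).
    """

    pathway_id: str
    reactions: list[Reaction]
    adjacency: np.ndarray
    merge_map: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        n = len(self.reactions)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match reaction count")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("adjacency must have zero diagonal")
        if not self.merge_map:
            self.merge_map = {r.reaction_id: (r.reaction_id,) for r in self.reactions}

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.reaction_id for r in self.reactions]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        """Unordered adjacent index pairs (a < b)."""
        a, b = np.nonzero(np.triu(self.adjacency))
        return list(zip(a.tolist(), b.tolist()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_reactions))
        g.add_edges_from(self.edges())
        return g


def _neighbors(a: Reaction, b: Reaction, treat_reversible: bool) -> bool:
    if a.products & b.substrates:
        return True
    if treat_reversible and (b.products & a.substrates):
        return True
    return False


def build_pathway_graph(
    pathway_id: str,
    reactions: list[Reaction],
    treat_reversible: bool = True,
    exclude_metabolites: frozenset[str] | set[str] = frozenset(),
) -> PathwayGraph:
    """Build the reaction-neighborhood graph of one pathway.

    Two reactions are adjacent when a metabolite is the product of one and
    the substrate of the other; with ``treat_reversible`` (default) the rule
    is checked in both directions.  ``exclude_metabolites`` optionally drops
    currency compounds (ATP, H2O, ...) from the neighborhood computation; it
    is empty by default.

    Raises
    ------
    ValueError
        If reaction ids are duplicated within the pathway.
    """
    ids = [r.reaction_id for r in reactions]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate reaction ids in pathway {pathway_id!r}: {dup}")
    if exclude_metabolites:
        excl = frozenset(exclude_metabolites)
        reactions = [
            replace(r, substrates=r.substrates - excl, products=r.products - excl)
            for r in reactions
        ]
    n = len(reactions)
    m = np.zeros((n, n), dtype=np.int8)
    for a in range(n):
        for b in range(a + 1, n):
            if _neighbors(reactions[a], reactions[b], treat_reversible):
                m[a, b] = m[b, a] = 1
    return PathwayGraph(pathway_id, list(reactions), m)


def merge_duplicate_reactions(graph: PathwayGraph) -> PathwayGraph:
    """Collapse reactions carried by exactly the same (non-empty) gene set.

    Such reactions are indistinguishable on the expression level and are
    counted as one; the merged node inherits the union of its members'
    edges, metabolites and EC numbers.  Reactions without gene annotation
    are never merged.  The operation is idempotent.
    """
    groups: dict[frozenset[str], list[int]] = {}
    order: list[list[int]] = []
    for idx, r in enumerate(graph.reactions):
        if r.gene_ids:
            key = r.gene_ids
            if key in groups:
                groups[key].append(idx)
                continue
            groups[key] = [idx]
            order.append(groups[key])
        else:
            order.append([idx])

    if all(len(g) == 1 for g in order):
        return graph

    new_reactions: list[Reaction] = []
    new_map: dict[str, tuple[str, ...]] = {}
    for members in order:
        rs = [graph.reactions[i] for i in members]
        rid = rs[0].reaction_id
        merged = Reaction(
            reaction_id=rid,
            substrates=frozenset().union(*(r.substrates for r in rs)),
            products=frozenset().union(*(r.products for r in rs)),
            gene_ids=rs[0].gene_ids,
            ec_numbers=frozenset().union(*(r.ec_numbers for r in rs)),
        )
        new_reactions.append(merged)
        new_map[rid] = tuple(
            orig for i in members for orig in graph.merge_map[graph.reactions[i].reaction_id]
        )

    k = len(order)
    m = np.zeros((k, k), dtype=np.int8)
    for gi, mem_i in enumerate(order):
        for gj in range(gi + 1, k):
            mem_j = order[gj]
            if any(graph.adjacency[a, b] for a in mem_i for b in mem_j):
                m[gi, gj] = m[gj, gi] = 1
    return PathwayGraph(graph.pathway_id, new_reactions, m, merge_map=new_map)


def filter_pathways(pathways: list[PathwayGraph]) -> list[PathwayGraph]:
    """Drop pathways without any connected reaction (zero-edge graphs)."""
    return [p for p in pathways if p.n_edges > 0]
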