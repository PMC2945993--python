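"""Embedding pathway graphs on square lattice grids.

Each reaction is assigned to a distinct lattice point of an s x s grid so
that the total Manhattan length of network edges is minimized — a quadratic
assignment problem, here solved exactly as an integer linear program with
binary placement variables x[v,i,j] and linearized per-edge distance
variables.  Known subgraph motifs (stars, small cliques, short odd cycles,
low-degree trees) admit grid-independent lower bounds on their edge-length
sum; these are available as optional valid inequalities, as are symmetry
breaking constraints pinning one node to a fundamental domain of the grid's
dihedral symmetry group.

Three backends are provided: an exact ILP (HiGHS via scipy), an exhaustive
brute-force search used as oracle for small graphs, and a simulated
annealing heuristic for when exact solving is too expensive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .pathway_model import PathwayGraph

__all__ = [
    "GridSpec",
    "GridEmbedding",
    "MotifBound",
    "manhattan_distance",
    "default_grid",
    "total_edge_length",
    "embed_exact_ilp",
    "embed_bruteforce",
    "embed_heuristic",
    "motif_lower_bound",
    "detect_motifs",
    "combinatorial_lower_bound",
]

MOTIF_KINDS = ("star", "clique", "odd_cycle", "bounded_degree_tree")


@dataclass(frozen=True)
class GridSpec:
    """Square lattice of side ``side_length`` with points (i, j), 0-based."""

    side_length: int

    def __post_init__(self) -> None:
        if self.side_length < 1:
            raise ValueError("side_length must be >= 1")

    @property
    def points(self) -> list[tuple[int, int]]:
        s = self.side_length
        return [(i, j) for i in range(s) for j in range(s)]

    @property
    def n_points(self) -> int:
        return self.side_length**2


@dataclass
class GridEmbedding:
    """An injective placement of reactions on grid points.

    ``objective`` is the realized total Manhattan edge length; ``gap`` the
    ratio of the best proven lower bound to the objective (1.0 when the
    placement is proven optimal; by convention also 1.0 for objective 0).
    """

    pathway_id: str
    grid: GridSpec
    placement: dict[str, tuple[int, int]]
    objective: int
    proven_optimal: bool
    gap: float
    method: str = ""

    def __post_init__(self) -> None:
        coords = list(self.placement.values())
        if len(set(coords)) != len(coords):
            raise ValueError("placement must be injective")
        s = self.grid.side_length
        if any(not (0 <= i < s and 0 <= j < s) for i, j in coords):
            raise ValueError("placement outside grid")


@dataclass(frozen=True)
class MotifBound:
    """A motif subgraph and a lower bound on its total embedded edge length."""

    motif_kind: str
    node_set: frozenset[int]
    edges: tuple[tuple[int, int], ...]
    bound: int


def manhattan_distance(u: tuple[int, int], v: tuple[int, int]) -> int:
    return abs(u[0] - v[0]) + abs(u[1] - v[1])


def default_grid(graph: PathwayGraph, slack: bool = False) -> GridSpec:
    """Smallest square grid holding all reactions; ``slack`` adds one row/col."""
    n = graph.n_reactions
    if n < 1:
        raise ValueError("graph has no nodes")
    s = math.isqrt(n)
    if s * s < n:
        s += 1
    return GridSpec(s + 1 if slack else s)


def total_edge_length(graph: PathwayGraph, embedding: GridEmbedding) -> int:
    """Sum of Manhattan distances over adjacent reaction pairs."""
    missing = set(graph.reaction_ids) - set(embedding.placement)
    if missing:
        raise ValueError(f"unplaced reactions: {sorted(missing)}")
    ids = graph.reaction_ids
    return sum(
        manhattan_distance(embedding.placement[ids[a]], embedding.placement[ids[b]])
        for a, b in graph.edges()
    )


# ---------------------------------------------------------------------------
# motif lower bounds


def _min_motif_length(g: nx.Graph) -> int:
    """Exact minimal total edge length of a small graph on a generous grid."""
    n = g.number_of_nodes()
    side = math.ceil(math.sqrt(n)) + 1
    if n <= 7:
        return _bruteforce_optimum(g, side)[1]
    return _ilp_optimum(g, side)


@lru_cache(maxsize=None)
def motif_lower_bound(motif_kind: str, k: int) -> int:
    """Least total lattice edge length of a motif, independent of host graph.

    ``k`` is the number of leaves for a star, the clique size, the cycle
    length (odd, 3 or 5) or the edge count of a degree-<=4 tree.  Values are
    obtained once by exhaustive lattice optimization of the motif (stars in
    closed form: the k cheapest lattice points around the center) and cached.
    """
    if motif_kind == "star":
        if k < 1:
            raise ValueError("star needs >= 1 leaf")
        # 4*d lattice points lie at Manhattan distance d from the center
        total, d, remaining = 0, 1, k
        while remaining > 0:
            take = min(remaining, 4 * d)
            total += take * d
            remaining -= take
            d += 1
        return total
    if motif_kind == "clique":
        if not 2 <= k <= 10:
            raise ValueError("cliques supported for 2 <= k <= 10")
        return _min_motif_length(nx.complete_graph(k))
    if motif_kind == "odd_cycle":
        if k not in (3, 5):
            raise ValueError("odd cycles supported for lengths 3 and 5")
        return _min_motif_length(nx.cycle_graph(k))
    if motif_kind == "bounded_degree_tree":
        # every edge spans >= 1; attained by e.g. a lattice path, so the
        # edge count is the generic tree bound used here
        if k < 1:
            raise ValueError("tree needs >= 1 edge")
        return k
    raise ValueError(f"unsupported motif kind {motif_kind!r}")


def detect_motifs(graph: PathwayGraph, kinds: set[str] | tuple[str, ...]) -> list[MotifBound]:
    """Statically detect star/clique/odd-cycle/tree motifs with their bounds.

    Duplicated edge sets (e.g. a triangle found both as clique and as odd
    cycle) are reported once with the larger bound.
    """
    g = graph.to_networkx()
    found: dict[frozenset[frozenset[int]], MotifBound] = {}

    def add(kind: str, nodes: frozenset[int], edges: list[tuple[int, int]], bound: int) -> None:
        key = frozenset(frozenset(e) for e in edges)
        prev = found.get(key)
        if prev is None or bound > prev.bound:
            found[key] = MotifBound(kind, nodes, tuple(sorted(tuple(sorted(e)) for e in edges)), bound)

    if "star" in kinds:
        for v in g.nodes:
            deg = g.degree[v]
            if deg >= 2:
                edges = [(v, u) for u in g.neighbors(v)]
                add("star", frozenset([v, *g.neighbors(v)]), edges, motif_lower_bound("star", deg))
    if "clique" in kinds:
        for clique in nx.find_cliques(g):
            k = len(clique)
            if 3 <= k <= 10:
                edges = list(itertools.combinations(sorted(clique), 2))
                add("clique", frozenset(clique), edges, motif_lower_bound("clique", k))
    if "odd_cycle" in kinds:
        for cyc in nx.simple_cycles(g, length_bound=5):
            k = len(cyc)
            if k in (3, 5):
                edges = [(cyc[i], cyc[(i + 1) % k]) for i in range(k)]
                add("odd_cycle", frozenset(cyc), edges, motif_lower_bound("odd_cycle", k))
    if "bounded_degree_tree" in kinds:
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            if sub.number_of_edges() == 0:
                continue
            tree = nx.bfs_tree(sub, sorted(comp)[0]).to_undirected()
            if max(d for _, d in tree.degree) <= 4:
                edges = list(tree.edges)
                add(
                    "bounded_degree_tree",
                    frozenset(comp),
                    edges,
                    motif_lower_bound("bounded_degree_tree", tree.number_of_edges()),
                )
    return list(found.values())


def combinatorial_lower_bound(graph: PathwayGraph) -> int:
    """Solver-free lower bound on the optimal total edge length.

    Combines the trivial per-edge bound |E| with the star bounds around each
    node: summing the star bound of every node counts each edge twice, so
    half that sum is valid.
    """
    g = graph.to_networkx()
    ne = g.number_of_edges()
    if ne == 0:
        return 0
    star_sum = sum(motif_lower_bound("star", d) for _, d in g.degree if d >= 1)
    return max(ne, math.ceil(star_sum / 2))


# ---------------------------------------------------------------------------
# exact ILP backend (HiGHS via scipy.optimize.milp)


def _symmetry_domain(s: int) -> set[tuple[int, int]]:
    """Fundamental domain of the dihedral symmetry group of an s x s grid."""
    half = (s - 1) / 2
    return {(i, j) for i in range(s) for j in range(s) if i <= half and j <= half and i <= j}


def _build_ilp(
    edges: list[tuple[int, int]],
    n: int,
    s: int,
    motif_cuts: list[MotifBound],
    pinned_node: int | None,
):
    cells = [(i, j) for i in range(s) for j in range(s)]
    nc = s * s
    nxvars = n * nc
    nd = len(edges)
    edge_index = {frozenset(e): k for k, e in enumerate(edges)}

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lo: list[float] = []
    hi: list[float] = []
    r = 0

    def xi(v: int, c: int) -> int:
        return v * nc + c

    for v in range(n):  # each node placed exactly once
        rows.extend([r] * nc)
        cols.extend(xi(v, c) for c in range(nc))
        vals.extend([1.0] * nc)
        lo.append(1.0)
        hi.append(1.0)
        r += 1
    for c in range(nc):  # each cell used at most once
        rows.extend([r] * n)
        cols.extend(xi(v, c) for v in range(n))
        vals.extend([1.0] * n)
        lo.append(0.0)
        hi.append(1.0)
        r += 1
    # d_ab >= +-A +- B with A = i_a - i_b, B = j_a - j_b
    for e, (a, b) in enumerate(edges):
        for sa, sb in itertools.product((1, -1), repeat=2):
            rows.append(r)
            cols.append(nxvars + e)
            vals.append(1.0)
            for c, (i, j) in enumerate(cells):
                coef = sa * i + sb * j
                if coef:
                    rows.append(r)
                    cols.append(xi(a, c))
                    vals.append(-float(coef))
                    rows.append(r)
                    cols.append(xi(b, c))
                    vals.append(float(coef))
            lo.append(0.0)
            hi.append(np.inf)
            r += 1
    for mb in motif_cuts:  # sum of motif edge distances >= lb
        idx = [edge_index.get(frozenset(e)) for e in mb.edges]
        if any(k is None for k in idx):
            continue
        rows.extend([r] * len(idx))
        cols.extend(nxvars + k for k in idx)  # type: ignore[operator]
        vals.extend([1.0] * len(idx))
        lo.append(float(mb.bound))
        hi.append(np.inf)
        r += 1

    ub = np.concatenate([np.ones(nxvars), np.full(nd, 2.0 * (s - 1))])
    if pinned_node is not None:
        domain = _symmetry_domain(s)
        for c, pt in enumerate(cells):
            if pt not in domain:
                ub[xi(pinned_node, c)] = 0.0

    A = sparse.coo_matrix((vals, (rows, cols)), shape=(r, nxvars + nd))
    c_obj = np.zeros(nxvars + nd)
    c_obj[nxvars:] = 1.0
    integrality = np.concatenate([np.ones(nxvars), np.zeros(nd)])
    bounds = Bounds(np.zeros(nxvars + nd), ub)
    return A, np.array(lo), np.array(hi), c_obj, integrality, bounds, cells


def embed_exact_ilp(
    graph: PathwayGraph,
    grid: GridSpec | None = None,
    cuts: set[str] | tuple[str, ...] = (),
    symmetry_breaking: bool = False,
    time_limit: float = 300.0,
) -> GridEmbedding:
    """Minimize total Manhattan edge length by integer linear programming.

    Distance variables are created only for adjacent node pairs (pairs with
    adjacency 0 contribute nothing to the objective).  ``cuts`` selects motif
    families whose valid inequalities are added up front; they never change
    the optimum, only the relaxation bound.  ``symmetry_breaking`` restricts
    one maximum-degree node to a fundamental domain of the grid's
    translation/rotation/reflection symmetries, which also preserves the
    optimum.  If the time limit is hit, the best incumbent is returned with
    its proven gap.

    Raises
    ------
    ValueError
        If the grid cannot hold all nodes or an unknown cut family is named.
    """
    if grid is None:
        grid = default_grid(graph)
    n = graph.n_reactions
    s = grid.side_length
    if s * s < n:
        raise ValueError(f"grid {s}x{s} cannot hold {n} nodes")
    unknown = set(cuts) - set(MOTIF_KINDS)
    if unknown:
        raise ValueError(f"unknown motif kinds: {sorted(unknown)}")

    edges = graph.edges()
    ids = graph.reaction_ids
    if not edges:
        placement = {ids[v]: grid.points[v] for v in range(n)}
        return GridEmbedding(graph.pathway_id, grid, placement, 0, True, 1.0, "ilp")

    motif_cuts = detect_motifs(graph, set(cuts)) if cuts else []
    pinned = None
    if symmetry_breaking:
        g = graph.to_networkx()
        pinned = max(range(n), key=lambda v: (g.degree[v], -v))

    A, lo, hi, c_obj, integrality, bounds, cells = _build_ilp(edges, n, s, motif_cuts, pinned)
    res = milp(
        c_obj,
        constraints=LinearConstraint(A, lo, hi),
        integrality=integrality,
        bounds=bounds,
        options={"time_limit": time_limit},
    )
    if res.x is None:
        raise RuntimeError(f"ILP solve failed for pathway {graph.pathway_id!r}: {res.message}")

    nc = s * s
    placement: dict[str, tuple[int, int]] = {}
    for v in range(n):
        c = int(np.argmax(res.x[v * nc : (v + 1) * nc]))
        placement[ids[v]] = cells[c]
    objective = sum(
        manhattan_distance(placement[ids[a]], placement[ids[b]]) for a, b in edges
    )
    lower = res.mip_dual_bound if res.mip_dual_bound is not None else 0.0
    proven = bool(res.status == 0 and (res.mip_gap is None or res.mip_gap <= 1e-9))
    gap = 1.0 if proven else max(0.0, min(1.0, lower / objective)) if objective else 1.0
    return GridEmbedding(graph.pathway_id, grid, placement, objective, proven, gap, "ilp")


# ---------------------------------------------------------------------------
# brute-force oracle


def _bruteforce_optimum(g: nx.Graph, side: int) -> tuple[dict, int]:
    nodes = list(g.nodes)
    n = len(nodes)
    cells = [(i, j) for i in range(side) for j in range(side)]
    edges = [(nodes.index(u), nodes.index(v)) for u, v in g.edges]
    best_obj = None
    best = None
    for combo in itertools.permutations(cells, n):
        obj = sum(manhattan_distance(combo[a], combo[b]) for a, b in edges)
        if best_obj is None or obj < best_obj:
            best_obj = obj
            best = combo
    assert best is not None and best_obj is not None
    return {nodes[v]: best[v] for v in range(n)}, best_obj


def embed_bruteforce(
    graph: PathwayGraph, grid: GridSpec | None = None, cap: int = 7
) -> GridEmbedding:
    """Exhaustive search over all injective placements (test oracle).

    Refuses graphs with more than ``cap`` nodes — the search space grows as
    P(s^2, n).
    """
    if grid is None:
        grid = default_grid(graph)
    n = graph.n_reactions
    if n > cap:
        raise ValueError(f"brute force refused: {n} nodes exceeds cap {cap}")
    if grid.n_points < n:
        raise ValueError(f"grid {grid.side_length}x{grid.side_length} cannot hold {n} nodes")
    ids = graph.reaction_ids
    edges = graph.edges()
    best_obj: int | None = None
    best: tuple[tuple[int, int], ...] | None = None
    for combo in itertools.permutations(grid.points, n):
        obj = sum(manhattan_distance(combo[a], combo[b]) for a, b in edges)
        if best_obj is None or obj < best_obj:
            best_obj, best = obj, combo
    assert best is not None and best_obj is not None
    placement = {ids[v]: best[v] for v in range(n)}
    return GridEmbedding(graph.pathway_id, grid, placement, best_obj, True, 1.0, "bruteforce")


def _ilp_optimum(g: nx.Graph, side: int) -> int:
    nodes = list(g.nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    edges = [(idx[u], idx[v]) for u, v in g.edges]
    A, lo, hi, c_obj, integrality, bounds, _ = _build_ilp(edges, len(nodes), side, [], 0)
    res = milp(
        c_obj,
        constraints=LinearConstraint(A, lo, hi),
        integrality=integrality,
        bounds=bounds,
    )
    if res.x is None or res.status != 0:
        raise RuntimeError(f"motif optimization failed: {res.message}")
    return round(res.fun)


# ---------------------------------------------------------------------------
# simulated-annealing heuristic


def embed_heuristic(
    graph: PathwayGraph,
    grid: GridSpec | None = None,
    seed: int = 0,
    iterations: int = 10_000,
) -> GridEmbedding:
    """Randomized local search: swap/relocate moves with annealed acceptance.

    Deterministic given ``seed``.  The reported gap uses the solver-free
    combinatorial lower bound; if the incumbent attains that bound it is a
    certificate of optimality.
    """
    if grid is None:
        grid = default_grid(graph)
    n = graph.n_reactions
    s = grid.side_length
    if s * s < n:
        raise ValueError(f"grid {s}x{s} cannot hold {n} nodes")
    rng = np.random.default_rng(seed)
    ids = graph.reaction_ids
    edges = graph.edges()

    cells = grid.points
    perm = rng.permutation(len(cells))
    pos = [cells[k] for k in perm[:n]]
    free = [cells[k] for k in perm[n:]]

    adj_of: dict[int, list[int]] = {v: [] for v in range(n)}
    for a, b in edges:
        adj_of[a].append(b)
        adj_of[b].append(a)

    def node_cost(v: int, coords: list[tuple[int, int]]) -> int:
        return sum(manhattan_distance(coords[v], coords[u]) for u in adj_of[v])

    obj = sum(manhattan_distance(pos[a], pos[b]) for a, b in edges)
    best_pos, best_obj = list(pos), obj
    t0, t1 = max(1.0, obj / 4), 0.05
    for it in range(iterations):
        temp = t0 * (t1 / t0) ** (it / max(1, iterations - 1))
        if free and rng.random() < 0.3:
            v = int(rng.integers(n))
            k = int(rng.integers(len(free)))
            old = pos[v]
            before = node_cost(v, pos)
            pos[v] = free[k]
            delta = node_cost(v, pos) - before
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                obj += delta
                free[k] = old
            else:
                pos[v] = old
        else:
            v, u = rng.choice(n, size=2, replace=False)
            before = node_cost(v, pos) + node_cost(u, pos)
            pos[v], pos[u] = pos[u], pos[v]
            after = node_cost(v, pos) + node_cost(u, pos)
            # a shared edge v-u contributes identically before and after a swap
            delta = after - before
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                obj += delta
            else:
                pos[v], pos[u] = pos[u], pos[v]
        if obj < best_obj:
            best_obj, best_pos = obj, list(pos)

    placement = {ids[v]: best_pos[v] for v in range(n)}
    lb = combinatorial_lower_bound(graph)
    proven = best_obj == lb or best_obj == 0
    gap = 1.0 if proven else (lb / best_obj if best_obj else 1.0)
    return GridEmbedding(graph.pathway_id, grid, placement, best_obj, proven, gap, "heuristic")


def embed(
    graph: PathwayGraph,
    grid: GridSpec | None = None,
    backend: str = "ilp",
    cuts: set[str] | tuple[str, ...] = (),
    symmetry_breaking: bool = False,
    time_limit: float = 300.0,
    seed: int = 0,
    iterations: int = 10_000,
) -> GridEmbedding:
    """Dispatch to one of the embedding backends by name."""
    if backend == "ilp":
        return embed_exact_ilp(graph, grid, cuts, symmetry_breaking, time_limit)
    if backend == "bruteforce":
        return embed_bruteforce(graph, grid)
    if backend == "heuristic":
        return embed_heuristic(graph, grid, seed=seed, iterations=iterations)
    raise ValueError(f"unknown backend {backend!r} (expected ilp, bruteforce or heuristic)")
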