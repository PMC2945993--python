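"""Synthetic pathway networks and two-group expression with planted patterns.

The generator emulates the pipeline's real inputs: connected random
reaction networks (random spanning tree plus extra edges, with metabolites
synthesized to realize the adjacencies), gene-level log-ratio expression
with Gaussian noise, and a clinical table encoding the intended prognosis
labels.  Regulation patterns can be planted into chosen pathways for the
unfavorable group:

``block_up`` / ``block_down``
    a connected block of reactions shifted by +delta / -delta;
``switch``
    contrasting regulation of graph-adjacent reaction pairs (+delta on one,
    -delta on its neighbor) — the high-pass signal the wavelet features are
    designed to pick up;
``null``
    no shift anywhere.

A sensitivity benchmark compares the wavelet pipeline against the Fisher's
exact enrichment baseline (optionally the rank-enrichment baseline) on
replicated synthetic datasets and reports ROC-style operating points and
AUCs.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pathway_model import PathwayGraph, Reaction, build_pathway_graph

__all__ = [
    "SimulationDesign",
    "generate_pathways",
    "generate_expression",
    "clinical_table",
    "benchmark_sensitivity",
    "null_fwer",
    "planted_recovery_rate",
]

PATTERNS = ("null", "block_up", "block_down", "switch")


@dataclass(frozen=True)
class SimulationDesign:
    """Study conditions for one synthetic dataset.

    Defaults describe a moderate two-group cohort: six pathways of eight
    reactions (two genes each), 30 samples per prognosis group, unit
    log-ratio noise, and an effect of two noise SDs planted in one pathway.
    """

    n_pathways: int = 6
    reactions_per_pathway: int = 8
    genes_per_reaction: int = 2
    n_favorable: int = 30
    n_unfavorable: int = 30
    noise_sd: float = 1.0
    pattern: str = "switch"
    effect_size: float = 2.0
    n_planted: int = 1
    block_size: int = 4
    extra_edge_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pathways, self.reactions_per_pathway, self.genes_per_reaction,
               self.n_favorable, self.n_unfavorable) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.pattern != "null" and not 0 <= self.n_planted <= self.n_pathways:
            raise ValueError("n_planted must lie in [0, n_pathways]")

    @property
    def planted_ids(self) -> list[str]:
        if self.pattern == "null" or self.effect_size == 0:
            return []
        return [f"SP{k:02d}" for k in range(self.n_planted)]


def _random_tree_edges(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform random labeled tree via a random Pruefer sequence."""
    if n == 1:
        return []
    if n == 2:
        return [(0, 1)]
    prufer = rng.integers(0, n, size=n - 2)
    degree = np.ones(n, dtype=int)
    for v in prufer:
        degree[v] += 1
    edges = []
    leaves = [v for v in range(n) if degree[v] == 1]
    heapq.heapify(leaves)
    for v in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, int(v)))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, int(v))
    edges.append((heapq.heappop(leaves), heapq.heappop(leaves)))
    return edges


def generate_pathways(design: SimulationDesign) -> list[PathwayGraph]:
    """Connected random reaction networks realizing the design, seeded."""
    rng = np.random.default_rng(design.seed)
    n = design.reactions_per_pathway
    pathways = []
    for p in range(design.n_pathways):
        pid = f"SP{p:02d}"
        edges = set(map(tuple, map(sorted, _random_tree_edges(n, rng))))
        n_extra = round(design.extra_edge_fraction * max(0, n - 1))
        candidates = [
            (a, b) for a in range(n) for b in range(a + 1, n) if (a, b) not in edges
        ]
        if candidates and n_extra:
            picks = rng.choice(len(candidates), size=min(n_extra, len(candidates)),
                               replace=False)
            edges |= {candidates[k] for k in picks}
        substrates: dict[int, set[str]] = {v: set() for v in range(n)}
        products: dict[int, set[str]] = {v: set() for v in range(n)}
        for k, (a, b) in enumerate(sorted(edges)):
            met = f"{pid}_M{k:03d}"
            if rng.random() < 0.5:
                a, b = b, a
            products[a].add(met)
            substrates[b].add(met)
        reactions = []
        for v in range(n):
            if not substrates[v] and not products[v]:
                substrates[v] = {f"{pid}_M_iso{v}"}
            reactions.append(
                Reaction(
                    reaction_id=f"{pid}_R{v:02d}",
                    substrates=frozenset(substrates[v]),
                    products=frozenset(products[v]),
                    gene_ids=frozenset(
                        f"{pid}_R{v:02d}_G{g}" for g in range(design.genes_per_reaction)
                    ),
                    ec_numbers=frozenset({f"9.9.{p}.{v}"}),
                )
            )
        pathways.append(build_pathway_graph(pid, reactions))
    return pathways


def _connected_block(graph: PathwayGraph, size: int, rng: np.random.Generator) -> list[int]:
    """A connected set of node indices grown breadth-first from a random seed."""
    g = graph.to_networkx()
    start = int(rng.integers(graph.n_reactions))
    block = [start]
    frontier = sorted(g.neighbors(start))
    while len(block) < size and frontier:
        nxt = frontier.pop(int(rng.integers(len(frontier))))
        if nxt in block:
            continue
        block.append(nxt)
        frontier.extend(u for u in sorted(g.neighbors(nxt)) if u not in block)
    return block


def generate_expression(
    design: SimulationDesign, pathways: list[PathwayGraph]
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Gene expression, clinical table and ground truth for one dataset.

    Gene log-ratios are N(0, noise_sd^2); planted pathways receive the
    design's pattern on the genes of the affected reactions in unfavorable
    samples only.  Returns (expression genes x samples, clinical table,
    truth record).
    """
    rng = np.random.default_rng((design.seed, 1))
    genes: list[str] = []
    gene_owner: dict[str, tuple[str, str]] = {}
    for pw in pathways:
        for r in pw.reactions:
            for g in sorted(r.gene_ids):
                genes.append(g)
                gene_owner[g] = (pw.pathway_id, r.reaction_id)
    samples = [f"F{k:03d}" for k in range(design.n_favorable)] + [
        f"U{k:03d}" for k in range(design.n_unfavorable)
    ]
    unfav = np.array([s.startswith("U") for s in samples])
    values = rng.normal(0.0, design.noise_sd, size=(len(genes), len(samples)))

    truth: dict = {"design": design, "planted": {}}
    planted = set(design.planted_ids)
    by_id = {pw.pathway_id: pw for pw in pathways}
    for pid in sorted(planted):
        pw = by_id[pid]
        shifts: dict[str, float] = {}
        if design.pattern in ("block_up", "block_down"):
            sign = 1.0 if design.pattern == "block_up" else -1.0
            block = _connected_block(pw, min(design.block_size, pw.n_reactions), rng)
            for v in block:
                shifts[pw.reactions[v].reaction_id] = sign * design.effect_size
        elif design.pattern == "switch":
            edges = pw.edges()
            a, b = edges[int(rng.integers(len(edges)))]
            shifts[pw.reactions[a].reaction_id] = design.effect_size
            shifts[pw.reactions[b].reaction_id] = -design.effect_size
        truth["planted"][pid] = shifts
        for gi, g in enumerate(genes):
            owner_p, owner_r = gene_owner[g]
            if owner_p == pid and owner_r in shifts:
                values[gi, unfav] += shifts[owner_r]

    expr = pd.DataFrame(values, index=genes, columns=samples)
    expr.index.name = "gene_id"
    return expr, clinical_table(samples), truth


def clinical_table(samples: list[str]) -> pd.DataFrame:
    """Clinical rows encoding the intended labels (t=6 vs t=2 + metastasis)."""
    return pd.DataFrame(
        {
            "sample_id": samples,
            "time_recurrence_years": [2.0 if s.startswith("U") else 6.0 for s in samples],
            "metastasis": [1 if s.startswith("U") else 0 for s in samples],
        }
    )


# ---------------------------------------------------------------------------
# replicated evaluation: FWER under the null, planted-pattern recovery


def _replicate_seed(seed: int, rep: int) -> int:
    return int(np.random.SeedSequence((seed, rep)).generate_state(1)[0] % 2**31)


def _pathway_feature_pvalues(design, pathways, embeddings, rep_seed):
    """Best-feature raw p and feature count per pathway for one replicate."""
    from .expression_mapping import (
        UNFAVORABLE,
        label_samples,
        map_expression_to_reactions,
        paint_image_stack,
    )
    from .stats_ranking import wilcoxon_matrix
    from .wavelet_features import cascade, enumerate_nontrivial

    d = replace(design, seed=rep_seed)
    expr, clinical, _ = generate_expression(d, pathways)
    labels = label_samples(clinical)
    mask_u = (labels.reindex(expr.columns) == UNFAVORABLE).to_numpy()
    best: dict[str, float] = {}
    m = 0
    for pw in pathways:
        rvals, _ = map_expression_to_reactions(expr, pw)
        emb = embeddings[pw.pathway_id]
        stack, _ = paint_image_stack(emb, rvals)
        table = enumerate_nontrivial(
            cascade(stack, emb.placement, pw.pathway_id, list(expr.columns))
        )
        m += table.n_features
        p = wilcoxon_matrix(table.values, mask_u, ~mask_u)
        best[pw.pathway_id] = float(p.min()) if p.size else 1.0
    return best, m


def null_fwer(
    design: SimulationDesign,
    n_replicates: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    config=None,
) -> float:
    """Family-wise error rate over replicated null datasets.

    Pathway graphs and embeddings follow the design (pattern forced to
    ``null``); expression is redrawn per replicate.  Returns the fraction of
    replicates in which any feature stays below ``alpha`` after Bonferroni
    correction over all non-trivial features of that replicate.
    """
    from .pipeline import RunConfig, embed_pathways

    design = replace(design, pattern="null")
    pathways = generate_pathways(design)
    embeddings = embed_pathways(pathways, config or RunConfig(seed=seed))
    hits = 0
    for rep in range(n_replicates):
        best, m = _pathway_feature_pvalues(design, pathways, embeddings,
                                           _replicate_seed(seed, rep))
        if min(best.values()) * m <= alpha:
            hits += 1
    return hits / n_replicates


def planted_recovery_rate(
    design: SimulationDesign,
    n_replicates: int = 100,
    seed: int = 0,
    config=None,
) -> float:
    """Fraction of replicates in which a planted pathway ranks first.

    Ranking is by the best (smallest) raw p over each pathway's non-trivial
    features — the same order the full pipeline reports.
    """
    from .pipeline import RunConfig, embed_pathways

    planted = set(design.planted_ids)
    if not planted:
        raise ValueError("design plants no pathway")
    pathways = generate_pathways(design)
    embeddings = embed_pathways(pathways, config or RunConfig(seed=seed))
    hits = 0
    for rep in range(n_replicates):
        best, _ = _pathway_feature_pvalues(design, pathways, embeddings,
                                           _replicate_seed(seed, rep))
        top = min(best, key=best.get)
        hits += top in planted
    return hits / n_replicates


# ---------------------------------------------------------------------------
# sensitivity benchmark


@dataclass
class BenchmarkResult:
    """ROC operating points and AUCs per method."""

    roc_table: pd.DataFrame
    auc: dict[str, float]
    scores: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def _auc_from_pvalues(p: np.ndarray, planted: np.ndarray) -> float:
    """AUC of the score -p via the rank-sum statistic (ties split)."""
    pos = p[planted]
    neg = p[~planted]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    wins = (pos[:, None] < neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (pos.size * neg.size))


def benchmark_sensitivity(
    design: SimulationDesign,
    methods: tuple[str, ...] = ("gridwave", "fisher"),
    n_replicates: int = 50,
    seed: int = 0,
    thresholds: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5),
    rank_enrichment_permutations: int = 200,
) -> BenchmarkResult:
    """Planted-pathway recovery of each method across replicated datasets.

    Pathway graphs (and their embeddings) follow the design and stay fixed
    across replicates; expression is redrawn per replicate.  Each method
    scores every pathway with a p-value (gridwave: best raw non-trivial
    feature p; fisher: DE-gene enrichment; rank_enrichment: permutation p);
    sensitivity/specificity are computed at each threshold and AUC from the
    full score ordering.
    """
    from .pipeline import RunConfig, analyze, embed_pathways
    from .expression_mapping import label_samples
    from .stats_ranking import (
        differential_genes,
        fisher_enrichment,
        rank_enrichment_baseline,
    )

    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    unknown = set(methods) - {"gridwave", "fisher", "rank_enrichment"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    base = replace(design, seed=design.seed)
    pathways = generate_pathways(base)
    planted = set(base.planted_ids)
    config = RunConfig(seed=seed)
    embeddings = embed_pathways(pathways, config) if "gridwave" in methods else {}
    rows = []
    for rep in range(n_replicates):
        d = replace(base, seed=int(np.random.SeedSequence((seed, rep)).generate_state(1)[0] % 2**31))
        expr, clinical, _ = generate_expression(d, pathways)
        labels = label_samples(clinical)
        if "gridwave" in methods:
            res, _, _ = analyze(pathways, expr, labels, config, embeddings=embeddings)
            for r in res:
                rows.append(("gridwave", rep, r.pathway_id, r.pathway_id in planted, r.p_raw))
        if "fisher" in methods or "rank_enrichment" in methods:
            universe = set(expr.index)
            de = differential_genes(expr, labels) if "fisher" in methods else set()
            for pw in pathways:
                pw_genes = set().union(*(r.gene_ids for r in pw.reactions))
                if "fisher" in methods:
                    p = fisher_enrichment(de, pw_genes, universe)
                    rows.append(("fisher", rep, pw.pathway_id, pw.pathway_id in planted, p))
                if "rank_enrichment" in methods:
                    _, p = rank_enrichment_baseline(
                        expr, labels, pw_genes,
                        n_permutations=rank_enrichment_permutations,
                        seed=(seed + 7919 * rep) % 2**31,
                    )
                    rows.append(
                        ("rank_enrichment", rep, pw.pathway_id, pw.pathway_id in planted, p)
                    )

    scores = pd.DataFrame(rows, columns=["method", "replicate", "pathway", "planted", "p"])
    roc_rows = []
    auc = {}
    for method, grp in scores.groupby("method"):
        p = grp["p"].to_numpy()
        is_planted = grp["planted"].to_numpy(dtype=bool)
        auc[method] = _auc_from_pvalues(p, is_planted)
        for thr in thresholds:
            sens = float(np.mean(p[is_planted] <= thr)) if is_planted.any() else float("nan")
            spec = float(np.mean(p[~is_planted] > thr)) if (~is_planted).any() else float("nan")
            roc_rows.append((method, thr, sens, spec))
    roc = pd.DataFrame(roc_rows, columns=["method", "threshold", "sensitivity", "specificity"])
    return BenchmarkResult(roc, auc, scores)
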