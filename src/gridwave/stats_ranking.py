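"""Feature testing, pathway ranking and enrichment baselines.

Wavelet features are compared between the favorable and unfavorable groups
with two-sided Wilcoxon rank-sum tests; the best (smallest) raw p-value per
pathway is Bonferroni-corrected over the family of all non-trivial features
tested.  A pathway is called significant when its adjusted best-feature
p-value passes alpha AND it contains more than ``min_reactions``
differentially regulated reactions (duplicate-gene-set reactions counted
once).  Fisher's exact enrichment of differentially expressed genes and a
simplified permutation-based rank-enrichment score serve as gene-set
baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_mapping import FAVORABLE, UNFAVORABLE
from .wavelet_features import FeatureDescriptor, FeatureTable

__all__ = [
    "PathwayResult",
    "wilcoxon_rank_sum",
    "wilcoxon_matrix",
    "bonferroni",
    "per_reaction_regulation",
    "rank_pathways",
    "results_frame",
    "fisher_enrichment",
    "differential_genes",
    "rank_enrichment_baseline",
]


@dataclass
class PathwayResult:
    """Per-pathway outcome: best feature, p-values and regulation counts."""

    pathway_id: str
    best_feature: FeatureDescriptor | None
    p_raw: float
    p_adjusted: float
    n_reactions: int
    n_diff_regulated: int
    n_up: int
    n_down: int
    significant: bool


def wilcoxon_rank_sum(group_a, group_b, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``exact`` enumerates the null distribution (refused with ties, falling
    back to the approximation); ``normal_approx`` uses the tie-corrected
    normal approximation; ``auto`` picks exact for n_a + n_b <= 20 without
    ties.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "exact" and has_ties:
        warnings.warn("ties present: exact Wilcoxon falls back to normal approximation")
        mode = "normal_approx"
    if mode == "auto":
        mode = "exact" if (a.size + b.size <= 20 and not has_ties) else "normal_approx"
    method = "exact" if mode == "exact" else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def wilcoxon_matrix(values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for a features x samples matrix.

    Uses the tie-corrected normal approximation (suitable for the group
    sizes of a cohort comparison); rows with zero rank variance get p = 1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be 2-dimensional")
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both groups must be non-empty")
    if values.shape[0] == 0:
        return np.empty(0)
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(
            values[:, mask_a], values[:, mask_b], alternative="two-sided",
            method="asymptotic", axis=1,
        )
    p = np.asarray(res.pvalue, dtype=float)
    return np.nan_to_num(p, nan=1.0)


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment min(1, p * m) over a family of size ``m``."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError("family size m must cover all tested p-values")
    return np.minimum(1.0, p * m)


def per_reaction_regulation(
    reaction_values: pd.DataFrame,
    measured: pd.Series,
    labels: pd.Series,
    alpha: float = 0.05,
) -> pd.Series:
    """Classify each reaction as up/down/unchanged in the unfavorable group.

    Two-sided rank-sum at the (uncorrected) per-reaction ``alpha``;
    direction is the sign of median(unfavorable) - median(favorable).
    Unmeasured reactions are always unchanged.
    """
    lab = labels.reindex(reaction_values.columns)
    mask_u = (lab == UNFAVORABLE).to_numpy()
    mask_f = (lab == FAVORABLE).to_numpy()
    vals = reaction_values.to_numpy(dtype=float)
    p = wilcoxon_matrix(vals, mask_u, mask_f)
    med_diff = np.median(vals[:, mask_u], axis=1) - np.median(vals[:, mask_f], axis=1)
    out = np.where(
        (p <= alpha) & measured.to_numpy() & (med_diff != 0),
        np.where(med_diff > 0, "up", "down"),
        "unchanged",
    )
    return pd.Series(out, index=reaction_values.index, name="regulation")


def rank_pathways(
    feature_tables: dict[str, FeatureTable],
    reaction_tables: dict[str, tuple[pd.DataFrame, pd.Series]],
    labels: pd.Series,
    alpha: float = 0.05,
    min_reactions: int = 3,
    family_scope: str = "global",
    reaction_alpha: float = 0.05,
) -> list[PathwayResult]:
    """Rank pathways by their best discriminating wavelet feature.

    ``feature_tables`` maps pathway id to its (non-trivial) FeatureTable;
    ``reaction_tables`` to the merged-graph reaction values and measured
    mask used for the regulation counts.  The Bonferroni family is all
    features across pathways (``global``, default) or per pathway
    (``per_pathway``).  ``min_reactions`` is strict: a pathway needs MORE
    than this many differentially regulated reactions to be significant.
    """
    if family_scope not in ("global", "per_pathway"):
        raise ValueError(f"unknown family_scope {family_scope!r}")
    m_global = sum(t.n_features for t in feature_tables.values())
    results: list[PathwayResult] = []
    for pid, table in feature_tables.items():
        rvals, measured = reaction_tables[pid]
        lab = labels.reindex(table.sample_ids)
        mask_u = (lab == UNFAVORABLE).to_numpy()
        mask_f = (lab == FAVORABLE).to_numpy()
        reg = per_reaction_regulation(rvals, measured, labels, alpha=reaction_alpha)
        n_up = int((reg == "up").sum())
        n_down = int((reg == "down").sum())
        if table.n_features == 0:
            results.append(
                PathwayResult(pid, None, 1.0, 1.0, rvals.shape[0],
                              n_up + n_down, n_up, n_down, False)
            )
            continue
        p = wilcoxon_matrix(table.values, mask_u, mask_f)
        best = int(np.argmin(p))
        m = m_global if family_scope == "global" else table.n_features
        p_adj = float(bonferroni(p[best], m)[0])
        n_diff = n_up + n_down
        results.append(
            PathwayResult(
                pathway_id=pid,
                best_feature=table.descriptors[best],
                p_raw=float(p[best]),
                p_adjusted=p_adj,
                n_reactions=rvals.shape[0],
                n_diff_regulated=n_diff,
                n_up=n_up,
                n_down=n_down,
                significant=bool(p_adj <= alpha and n_diff > min_reactions),
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.pathway_id))
    return results


def results_frame(results: list[PathwayResult]) -> pd.DataFrame:
    """Ranked results as a table: rank, pathway, counts, p-values."""
    rows = [
        {
            "rank": k + 1,
            "pathway": r.pathway_id,
            "n_diff_regulated": r.n_diff_regulated,
            "n_reactions": r.n_reactions,
            "n_down": r.n_down,
            "n_up": r.n_up,
            "p_value": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "significant": r.significant,
        }
        for k, r in enumerate(results)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "pathway", "n_diff_regulated", "n_reactions",
            "n_down", "n_up", "p_value", "p_adjusted", "significant",
        ],
    )


# ---------------------------------------------------------------------------
# gene-set baselines


def differential_genes(expr: pd.DataFrame, labels: pd.Series, alpha: float = 0.05) -> set[str]:
    """Genes differentially expressed between the groups (rank-sum p <= alpha)."""
    lab = labels.reindex(expr.columns)
    mask_u = (lab == UNFAVORABLE).to_numpy()
    mask_f = (lab == FAVORABLE).to_numpy()
    p = wilcoxon_matrix(expr.to_numpy(dtype=float), mask_u, mask_f)
    return set(np.asarray(expr.index)[p <= alpha])


def fisher_enrichment(de_genes: set, pathway_genes: set, universe: set) -> float:
    """Two-sided Fisher's exact p for DE-gene enrichment of a pathway."""
    if not universe:
        raise ValueError("universe must be non-empty")
    if not pathway_genes <= universe:
        raise ValueError("pathway_genes must be a subset of the universe")
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    a = len(de_genes & pathway_genes)
    b = len(pathway_genes) - a
    c = len(de_genes) - a
    d = len(universe) - len(pathway_genes) - c
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _enrichment_score(stat: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov-style running-sum enrichment score."""
    order = np.argsort(-stat, kind="stable")
    hits = in_set[order]
    w = np.abs(stat[order])
    nh = hits.sum()
    n = stat.size
    if nh == 0 or nh == n:
        return 0.0
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hits.astype(float)
        denom = float(nh)
    running = np.cumsum(hit_w / denom - (~hits) / (n - nh))
    return float(running[np.argmax(np.abs(running))])


def rank_enrichment_baseline(
    expr: pd.DataFrame,
    labels: pd.Series,
    pathway_genes: set[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Simplified rank-based gene-set enrichment with a permutation null.

    Genes are ranked by a signed rank-sum z statistic
    (unfavorable vs favorable); the pathway's weighted running-sum
    enrichment score is compared two-sidedly against scores under sample
    label permutation.  Returns (enrichment_score, p_value).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    lab = labels.reindex(expr.columns)
    keep = lab.isin([FAVORABLE, UNFAVORABLE]).to_numpy()
    vals = expr.to_numpy(dtype=float)[:, keep]
    lab = lab[keep]
    mask_u = (lab == UNFAVORABLE).to_numpy()
    n_u = int(mask_u.sum())
    if n_u == 0 or n_u == vals.shape[1]:
        raise ValueError("both groups must be non-empty")
    in_set = np.isin(np.asarray(expr.index), sorted(pathway_genes))

    ranks = stats.rankdata(vals, axis=1)
    n = vals.shape[1]

    def zstat(mask: np.ndarray) -> np.ndarray:
        nu = mask.sum()
        r = ranks[:, mask].sum(axis=1)
        mu = nu * (n + 1) / 2
        sigma = np.sqrt(nu * (n - nu) * (n + 1) / 12)
        return (r - mu) / sigma

    es_obs = _enrichment_score(zstat(mask_u), in_set)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_u, replace=False)] = True
        if abs(_enrichment_score(zstat(perm), in_set)) >= abs(es_obs):
            count += 1
    return es_obs, (count + 1) / (n_permutations + 1)
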