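"""End-to-end analysis: graphs -> embeddings -> features -> ranked pathways."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .expression_mapping import (
    FAVORABLE,
    UNFAVORABLE,
    label_samples,
    map_expression_to_reactions,
    paint_image_stack,
)
from .grid_embedding import GridEmbedding, default_grid, embed
from .pathway_model import PathwayGraph, filter_pathways, merge_duplicate_reactions
from .stats_ranking import PathwayResult, rank_pathways
from .wavelet_features import FeatureTable, cascade, enumerate_nontrivial

__all__ = ["RunConfig", "embed_pathways", "analyze"]

logger = logging.getLogger("gridwave")


@dataclass
class RunConfig:
    """All knobs of one analysis run (recorded in output provenance)."""

    alpha: float = 0.05
    min_reactions: int = 3
    grid_slack: bool = False
    backend: str = "ilp"
    cuts: tuple[str, ...] = ()
    symmetry_breaking: bool = False
    time_limit: float = 300.0
    offsets_mode: str = "all4"
    aggregation: str = "mean"
    family_scope: str = "global"
    reaction_alpha: float = 0.05
    merge_duplicates: bool = True
    heuristic_iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def as_dict(self) -> dict:
        return dict(vars(self))


def embed_pathways(
    pathways: list[PathwayGraph], config: RunConfig | None = None
) -> dict[str, GridEmbedding]:
    """Embed every pathway on its default grid with the configured backend."""
    config = config or RunConfig()
    out: dict[str, GridEmbedding] = {}
    for pw in pathways:
        grid = default_grid(pw, slack=config.grid_slack)
        emb = embed(
            pw,
            grid,
            backend=config.backend,
            cuts=config.cuts,
            symmetry_breaking=config.symmetry_breaking,
            time_limit=config.time_limit,
            seed=config.seed,
            iterations=config.heuristic_iterations,
        )
        logger.info(
            "embedded %s: |V|=%d grid=%dx%d objective=%d gap=%.3f",
            pw.pathway_id, pw.n_reactions, grid.side_length, grid.side_length,
            emb.objective, emb.gap,
        )
        out[pw.pathway_id] = emb
    return out


def analyze(
    pathways: list[PathwayGraph],
    expr: pd.DataFrame,
    labels: pd.Series | pd.DataFrame,
    config: RunConfig | None = None,
    embeddings: dict[str, GridEmbedding] | None = None,
) -> tuple[list[PathwayResult], dict[str, FeatureTable], dict[str, GridEmbedding]]:
    """Run the full pattern-recognition pipeline on one dataset.

    ``labels`` may be a clinical table (labelled here) or a ready label
    Series.  Precomputed ``embeddings`` may be passed when re-analyzing new
    expression on the same pathway set.  Returns the ranked results plus
    the non-trivial feature tables and embeddings used.
    """
    config = config or RunConfig()
    if isinstance(labels, pd.DataFrame):
        labels = label_samples(labels)
    keep = labels[labels.isin([FAVORABLE, UNFAVORABLE])]
    n_f = int((keep == FAVORABLE).sum())
    n_u = int((keep == UNFAVORABLE).sum())
    if n_f < 2 or n_u < 2:
        raise ValueError(f"need >= 2 samples per group, got {n_f} favorable / {n_u} unfavorable")
    samples = [s for s in expr.columns if s in keep.index]
    expr = expr[samples]

    retained = filter_pathways(pathways)
    if len(retained) < len(pathways):
        logger.warning("discarded %d pathway(s) without connected reactions",
                       len(pathways) - len(retained))
    if config.merge_duplicates:
        retained = [merge_duplicate_reactions(p) for p in retained]
    retained = filter_pathways(retained)

    feature_tables: dict[str, FeatureTable] = {}
    reaction_tables: dict[str, tuple[pd.DataFrame, pd.Series]] = {}
    embeddings = dict(embeddings) if embeddings else {}
    for pw in retained:
        try:
            rvals, measured = map_expression_to_reactions(expr, pw, config.aggregation)
        except ValueError as err:
            logger.warning("skipping pathway %s: %s", pw.pathway_id, err)
            continue
        if pw.pathway_id not in embeddings:
            embeddings[pw.pathway_id] = embed_pathways([pw], config)[pw.pathway_id]
        emb = embeddings[pw.pathway_id]
        stack, _ = paint_image_stack(emb, rvals)
        table = cascade(stack, emb.placement, pw.pathway_id, samples, config.offsets_mode)
        table = enumerate_nontrivial(table)
        feature_tables[pw.pathway_id] = table
        reaction_tables[pw.pathway_id] = (rvals, measured)
        logger.info("pathway %s: %d non-trivial features", pw.pathway_id, table.n_features)

    results = rank_pathways(
        feature_tables,
        reaction_tables,
        keep,
        alpha=config.alpha,
        min_reactions=config.min_reactions,
        family_scope=config.family_scope,
        reaction_alpha=config.reaction_alpha,
    )
    return results, feature_tables, embeddings
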