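"""From clinical tables and gene expression to reaction images.

Samples are split by prognosis: recurrence-free beyond 5 years is
favorable, recurrence before 3 years together with metastasis is
unfavorable, everything else (including the exact boundaries) is ambiguous
and discarded.  Gene-level log-ratio expression is aggregated per reaction
over the reaction's annotated genes and painted onto the embedded grid,
with zeros in cells that carry no reaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_embedding import GridEmbedding
from .pathway_model import PathwayGraph

__all__ = [
    "FAVORABLE",
    "UNFAVORABLE",
    "DISCARDED",
    "ReactionImage",
    "label_samples",
    "map_expression_to_reactions",
    "paint_reaction_image",
    "paint_image_stack",
]

FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"
DISCARDED = "discarded"


@dataclass
class ReactionImage:
    """One sample's expression painted on the embedding grid."""

    pathway_id: str
    sample_id: str
    matrix: np.ndarray
    occupied: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.matrix.shape != self.occupied.shape:
            raise ValueError("matrix and occupied mask shapes differ")
        if np.any(self.matrix[~self.occupied] != 0):
            raise ValueError("cells outside the occupied mask must be exactly 0")


def label_samples(clinical: pd.DataFrame) -> pd.Series:
    """Assign favorable/unfavorable/discarded prognosis labels.

    Expects columns ``sample_id``, ``time_recurrence_years`` and
    ``metastasis`` (truthy/0-1).  Favorable: recurrence time strictly above
    5 years.  Unfavorable: strictly below 3 years with metastasis.  All
    other samples — including rows with missing fields and the boundary
    times 3 and 5 exactly — are discarded.
    """
    required = {"sample_id", "time_recurrence_years", "metastasis"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table lacks columns: {sorted(missing)}")
    t = pd.to_numeric(clinical["time_recurrence_years"], errors="coerce")
    met = clinical["metastasis"]
    met_bool = met.map(lambda v: bool(v) if pd.notna(v) else None)

    labels = []
    for tv, mv in zip(t, met_bool):
        if pd.isna(tv) or mv is None:
            labels.append(DISCARDED)
        elif tv > 5:
            labels.append(FAVORABLE)
        elif tv < 3 and mv:
            labels.append(UNFAVORABLE)
        else:
            labels.append(DISCARDED)
    out = pd.Series(labels, index=clinical["sample_id"].astype(str).values, name="label")
    out.index.name = "sample_id"
    return out


def map_expression_to_reactions(
    expr: pd.DataFrame,
    graph: PathwayGraph,
    aggregation: str = "mean",
) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate gene expression to reaction-level values.

    ``expr`` is genes x samples.  Per reaction, the values of its measured
    genes are combined by ``aggregation`` (mean, median or max).  Reactions
    with no measured gene receive the neutral log-ratio 0 and are flagged
    unmeasured in the returned mask so that feature triviality can be
    decided structurally rather than by value.

    Returns
    -------
    (reaction_values, measured)
        ``reaction_values``: reactions x samples DataFrame;
        ``measured``: boolean Series indexed by reaction_id.

    Raises
    ------
    ValueError
        If no reaction of the pathway has any measured gene.
    """
    if aggregation not in ("mean", "median", "max"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if expr.index.has_duplicates or expr.columns.has_duplicates:
        raise ValueError("expression matrix has duplicate gene or sample ids")
    values = np.zeros((graph.n_reactions, expr.shape[1]))
    measured = np.zeros(graph.n_reactions, dtype=bool)
    gene_index = set(expr.index)
    for k, reaction in enumerate(graph.reactions):
        genes = sorted(reaction.gene_ids & gene_index)
        if not genes:
            continue
        sub = expr.loc[genes].to_numpy(dtype=float)
        agg = {"mean": np.nanmean, "median": np.nanmedian, "max": np.nanmax}[aggregation]
        row = agg(sub, axis=0)
        if np.all(np.isnan(row)):
            continue
        values[k] = np.nan_to_num(row)
        measured[k] = True
    if not measured.any():
        raise ValueError(
            f"pathway {graph.pathway_id!r}: no overlap between expression genes "
            "and reaction annotations"
        )
    rv = pd.DataFrame(values, index=graph.reaction_ids, columns=expr.columns)
    return rv, pd.Series(measured, index=graph.reaction_ids, name="measured")


def paint_reaction_image(
    embedding: GridEmbedding, reaction_values: pd.Series, sample_id: str = ""
) -> ReactionImage:
    """Paint one sample's reaction values onto the embedding grid."""
    missing = set(embedding.placement) - set(reaction_values.index)
    if missing:
        raise ValueError(f"values missing for placed reactions: {sorted(missing)}")
    s = embedding.grid.side_length
    mat = np.zeros((s, s))
    occ = np.zeros((s, s), dtype=bool)
    for rid, (i, j) in embedding.placement.items():
        mat[i, j] = reaction_values[rid]
        occ[i, j] = True
    return ReactionImage(embedding.pathway_id, sample_id, mat, occ)


def paint_image_stack(
    embedding: GridEmbedding, reaction_values: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Paint all samples at once: (n_samples, side, side) plus occupied mask."""
    missing = set(embedding.placement) - set(reaction_values.index)
    if missing:
        raise ValueError(f"values missing for placed reactions: {sorted(missing)}")
    s = embedding.grid.side_length
    n_samples = reaction_values.shape[1]
    stack = np.zeros((n_samples, s, s))
    occ = np.zeros((s, s), dtype=bool)
    for rid, (i, j) in embedding.placement.items():
        stack[:, i, j] = reaction_values.loc[rid].to_numpy(dtype=float)
        occ[i, j] = True
    return stack, occ
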