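"""Readers and writers for the pipeline's file formats.

Formats
-------
Pathway TSV
    One row per reaction-metabolite link:
    ``pathway_id  reaction_id  role(substrate|product)  metabolite_id
    gene_ids(;-separated)  ec_numbers(;-separated)``; header required.
KGML
    Optional KEGG XML reader mapping ``<reaction>`` substrate/product
    entries (and gene entries referring to them) to the same structures.
Expression TSV
    First column gene id, remaining columns samples; missing as empty/NA.
Clinical TSV
    ``sample_id  time_recurrence_years  metastasis(0/1)``.
Embeddings JSON
    Per pathway: side length, 0-based (row i, column j) placements,
    objective, optimality flag and gap.
Results / feature TSV
    Written with a ``#``-prefixed provenance header (config and seed), so
    downstream numbers stay tied to the embedding that produced them.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from lxml import etree

from .grid_embedding import GridEmbedding, GridSpec
from .pathway_model import PathwayGraph, Reaction, build_pathway_graph
from .wavelet_features import FeatureTable

__all__ = [
    "read_pathway_tsv",
    "write_pathway_tsv",
    "read_kgml",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "write_embeddings_json",
    "read_embeddings_json",
    "write_feature_tsv",
    "write_results_tsv",
    "read_results_tsv",
]

PATHWAY_COLUMNS = [
    "pathway_id", "reaction_id", "role", "metabolite_id", "gene_ids", "ec_numbers",
]


def _split(cell: str) -> frozenset[str]:
    if not cell or pd.isna(cell):
        return frozenset()
    return frozenset(x for x in str(cell).split(";") if x)


def read_pathway_tsv(path: str | Path, treat_reversible: bool = True) -> list[PathwayGraph]:
    """Parse the pathway link table into one graph per pathway.

    Raises ``ValueError`` naming the offending line on malformed rows.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PATHWAY_COLUMNS:
            raise ValueError(
                f"{path}:1: expected header {PATHWAY_COLUMNS}, got {header}"
            )
        per_pathway: dict[str, dict[str, dict]] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            pid, rid, role, met, genes, ecs = parts
            if role not in ("substrate", "product"):
                raise ValueError(f"{path}:{lineno}: role must be substrate|product, got {role!r}")
            rec = per_pathway.setdefault(pid, {}).setdefault(
                rid,
                {"substrates": set(), "products": set(), "gene_ids": set(), "ec_numbers": set()},
            )
            rec["substrates" if role == "substrate" else "products"].add(met)
            rec["gene_ids"] |= _split(genes)
            rec["ec_numbers"] |= _split(ecs)
    graphs = []
    for pid, reactions in per_pathway.items():
        rs = [
            Reaction(rid, frozenset(rec["substrates"]), frozenset(rec["products"]),
                     frozenset(rec["gene_ids"]), frozenset(rec["ec_numbers"]))
            for rid, rec in reactions.items()
        ]
        graphs.append(build_pathway_graph(pid, rs, treat_reversible=treat_reversible))
    return graphs


def write_pathway_tsv(pathways: list[PathwayGraph], path: str | Path) -> None:
    rows = []
    for pw in pathways:
        for r in pw.reactions:
            genes = ";".join(sorted(r.gene_ids))
            ecs = ";".join(sorted(r.ec_numbers))
            for met in sorted(r.substrates):
                rows.append((pw.pathway_id, r.reaction_id, "substrate", met, genes, ecs))
            for met in sorted(r.products):
                rows.append((pw.pathway_id, r.reaction_id, "product", met, genes, ecs))
    pd.DataFrame(rows, columns=PATHWAY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_kgml(path: str | Path, treat_reversible: bool = True) -> PathwayGraph:
    """Read one KEGG KGML pathway file (reactions, substrates, products, genes)."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    pid = root.get("name", root.get("number", "kgml"))
    genes_by_reaction: dict[str, set[str]] = {}
    for entry in root.findall("entry"):
        if entry.get("type") == "gene" and entry.get("reaction"):
            for rname in entry.get("reaction", "").split():
                genes_by_reaction.setdefault(rname, set()).update(
                    entry.get("name", "").split()
                )
    reactions = []
    seen = set()
    for rx in root.findall("reaction"):
        rname = rx.get("name", "")
        if rname in seen:
            continue
        seen.add(rname)
        subs = frozenset(s.get("name", "") for s in rx.findall("substrate"))
        prods = frozenset(p.get("name", "") for p in rx.findall("product"))
        reactions.append(
            Reaction(rname, subs, prods, frozenset(genes_by_reaction.get(rname, set())))
        )
    return build_pathway_graph(pid, reactions, treat_reversible=treat_reversible)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    expr.index = expr.index.astype(str)
    if expr.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    return expr


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "time_recurrence_years", "metastasis"}
    if not required <= set(clin.columns):
        raise ValueError(f"{path}: clinical table needs columns {sorted(required)}")
    return clin


def write_clinical_tsv(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def write_embeddings_json(
    embeddings: dict[str, GridEmbedding], path: str | Path, provenance: dict | None = None
) -> None:
    payload = {
        "provenance": provenance or {},
        "embeddings": [
            {
                "pathway_id": emb.pathway_id,
                "side_length": emb.grid.side_length,
                "placements": [
                    {"reaction_id": rid, "i": i, "j": j}
                    for rid, (i, j) in sorted(emb.placement.items())
                ],
                "objective": emb.objective,
                "proven_optimal": emb.proven_optimal,
                "gap": emb.gap,
                "method": emb.method,
            }
            for emb in embeddings.values()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_embeddings_json(path: str | Path) -> dict[str, GridEmbedding]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for rec in payload["embeddings"]:
        emb = GridEmbedding(
            pathway_id=rec["pathway_id"],
            grid=GridSpec(rec["side_length"]),
            placement={p["reaction_id"]: (p["i"], p["j"]) for p in rec["placements"]},
            objective=rec["objective"],
            proven_optimal=rec["proven_optimal"],
            gap=rec["gap"],
            method=rec.get("method", ""),
        )
        out[emb.pathway_id] = emb
    return out


def _provenance_header(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k} = {v}\n" for k, v in sorted(provenance.items()))


def write_feature_tsv(
    tables: dict[str, FeatureTable], path: str | Path, provenance: dict | None = None
) -> None:
    rows = []
    for pid, table in tables.items():
        for desc, vals in zip(table.descriptors, table.values):
            rows.append(
                {
                    "pathway": pid,
                    "level": desc.level,
                    "block_row": desc.block[0],
                    "block_col": desc.block[1],
                    "off_y": desc.offset[0],
                    "off_x": desc.offset[1],
                    "coeff_type": desc.coeff_type,
                    "support_size": len(desc.support),
                    **dict(zip(table.sample_ids, vals)),
                }
            )
    frame = pd.DataFrame(rows)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_provenance_header(provenance))
        frame.to_csv(fh, sep="\t", index=False)


def write_results_tsv(
    results_frame: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_provenance_header(provenance))
        results_frame.to_csv(fh, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
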