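"""Composition of externally detected co-expression modules by category.

Module detection itself (weighted-correlation network analysis with
iterative pruning) is consumed, not implemented: the input is its
gene-to-module output table (TSV: gene_id, module_id). Each gene belongs to
at most one module. Y-ome genes that are co-expressed with well-annotated
genes are the highest-priority targets for experimental characterization, so
they are ranked by the well-annotated fraction of their module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .types import Category

_COUNT_CATEGORIES = (
    Category.WELL_ANNOTATED.value,
    Category.YOME.value,
    Category.EXCLUDED.value,
)


@dataclass
class ModuleSummary:
    per_module: pd.DataFrame  # index module_id; columns well_annotated, yome, excluded, size
    totals: dict[str, int]
    n_modules: int
    unassigned_genes: list[str]
    unknown_genes: list[str] = field(default_factory=list)


def read_modules(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "module_id"} <= set(df.columns):
        raise ValueError(f"{path}: module table needs columns gene_id, module_id")
    return df


def summarize_modules(
    assignments: pd.DataFrame, categories: pd.DataFrame
) -> ModuleSummary:
    """Per-module and total gene counts by final category.

    A gene assigned to more than one module is a validation error. Genes in
    the category table but absent from the assignments are counted as
    unassigned; assigned genes missing from the category table are reported
    as unknown (they contribute to module sizes but to no category column).
    """
    dup = assignments["gene_id"][assignments["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"genes assigned to multiple modules: {sorted(set(dup))}")
    cat_map = dict(zip(categories["gene_id"], categories["category"]))
    unknown = sorted(g for g in assignments["gene_id"] if g not in cat_map)

    modules = sorted(assignments["module_id"].unique())
    rows = []
    for module_id in modules:
        members = assignments.loc[assignments["module_id"] == module_id, "gene_id"]
        counts = {c: 0 for c in _COUNT_CATEGORIES}
        for g in members:
            cat = cat_map.get(g)
            if cat in counts:
                counts[cat] += 1
        counts["size"] = len(members)
        rows.append(pd.Series(counts, name=module_id))
    per_module = (
        pd.DataFrame(rows)
        if rows
        else pd.DataFrame(columns=[*_COUNT_CATEGORIES, "size"])
    )
    totals = {c: int(per_module[c].sum()) if len(per_module) else 0 for c in _COUNT_CATEGORIES}
    assigned = set(assignments["gene_id"])
    unassigned = sorted(g for g in cat_map if g not in assigned)
    return ModuleSummary(
        per_module=per_module,
        totals=totals,
        n_modules=len(modules),
        unassigned_genes=unassigned,
        unknown_genes=unknown,
    )


def rank_candidate_genes(
    assignments: pd.DataFrame, categories: pd.DataFrame
) -> pd.DataFrame:
    """Rank y-ome genes by how well-annotated their module's company is.

    Sort key: fraction of well-annotated co-members (descending), then
    module size (descending), then gene_id (ascending) as a deterministic
    tie-break. Excluded genes are summarized elsewhere but never ranked.
    """
    summary = summarize_modules(assignments, categories)
    cat_map = dict(zip(categories["gene_id"], categories["category"]))
    rows = []
    for row in assignments.itertuples(index=False):
        if cat_map.get(row.gene_id) != Category.YOME.value:
            continue
        mod = summary.per_module.loc[row.module_id]
        size = int(mod["size"])
        others = size - 1
        frac_well = (mod[Category.WELL_ANNOTATED.value] / others) if others else 0.0
        rows.append(
            {
                "gene_id": row.gene_id,
                "module_id": row.module_id,
                "well_annotated_fraction": float(frac_well),
                "module_size": size,
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "module_id", "well_annotated_fraction", "module_size"]
    )
    return df.sort_values(
        by=["well_annotated_fraction", "module_size", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
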