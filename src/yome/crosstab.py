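"""Name-convention crosstab and external gene-set comparison.

Historically, unannotated open reading frames were given primary names
starting with 'y', but name and annotation status have drifted apart: many
'y'-named genes are now well-annotated and many y-ome genes carry non-'y'
names. The crosstab quantifies that drift. The gene-set comparison counts
how an external list (for example the gene content of a genome-scale
metabolic model) distributes over the final categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .types import FINAL_CATEGORIES


def yname_crosstab(categories: pd.DataFrame) -> pd.DataFrame:
    """2x3 table: primary name starts with 'y' (case-insensitive) x category.

    The prefix test uses the registry's primary name only, not synonyms;
    cells partition the registry.
    """
    cats = [c.value for c in FINAL_CATEGORIES]
    table = pd.DataFrame(0, index=["y_prefix", "non_y"], columns=cats)
    for row in categories.itertuples(index=False):
        prefix = "y_prefix" if str(row.primary_name).lower().startswith("y") else "non_y"
        table.loc[prefix, row.category] += 1
    return table


@dataclass
class GeneSetComparison:
    counts: dict[str, int]
    unmatched: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + len(self.unmatched)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def compare_gene_set(
    categories: pd.DataFrame, external: list[str]
) -> GeneSetComparison:
    """Overlap of an external gene list with the final categories.

    External identifiers are matched against gene_id first, then primary
    name (case-insensitive); unmatched identifiers are reported, so matched
    counts plus unmatched always sum to the external list size.
    """
    if not external:
        raise ValueError("external gene list is empty")
    by_id = dict(zip(categories["gene_id"], categories["category"]))
    by_name = {
        str(n).lower(): c
        for n, c in zip(categories["primary_name"], categories["category"])
    }
    counts = {c.value: 0 for c in FINAL_CATEGORIES}
    unmatched: list[str] = []
    for ident in external:
        cat = by_id.get(ident) or by_name.get(ident.lower())
        if cat is None:
            unmatched.append(ident)
        else:
            counts[cat] += 1
    return GeneSetComparison(counts=counts, unmatched=unmatched)
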