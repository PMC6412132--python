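"""Consensus across knowledge bases, exception heuristics and overrides.

Per-KB assignments for one gene are combined in a fixed evaluation order:

1. any ``excluded`` assignment (pseudogene / phantom gene track) wins —
   functional-evidence heuristics never resurrect an excluded gene;
2. EcoCyc's curated functional-evidence ontology (keywords ``assay``,
   ``reaction blocked in mutant``, ``traceable author statement to
   experimental support``) → ``well_annotated``;
3. a RegulonDB transcription-factor annotation with ``Strong`` evidence →
   ``well_annotated``;
4. EcoCyc and UniProt both voting ``well_annotated`` → ``well_annotated``;
5. an insertion element → ``well_annotated``;
6. agreement: every definite (non-``insufficient``) vote identical → that
   category. A gene with only ``insufficient`` votes defaults to the y-ome
   (lack of evidence is its definition) with a low-confidence flag;
7. definite votes disagree → the manual override decides, else the record is
   ``unresolved``.

``basis`` records the first rule that decided. Exceptions 2-5 all output
``well_annotated``, so their relative order affects only the recorded basis,
never the category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .categorize import RuleSet
from .types import (
    Basis,
    Category,
    CategoryAssignment,
    ConsensusRecord,
    FeatureType,
    FINAL_CATEGORIES,
    KBFeature,
    KnowledgeBase,
    ManualOverride,
)

logger = logging.getLogger(__name__)


class UnresolvedGenesError(ValueError):
    """Strict-mode failure: unresolved genes without manual overrides."""

    def __init__(self, gene_ids: list[str]):
        self.gene_ids = gene_ids
        super().__init__(
            f"{len(gene_ids)} unresolved gene(s) lack a manual override: "
            + ", ".join(gene_ids[:10])
            + ("..." if len(gene_ids) > 10 else "")
        )


def apply_consensus(
    assignments: list[CategoryAssignment],
    rules: RuleSet,
    override: ManualOverride | None = None,
) -> ConsensusRecord:
    """Combine one gene's per-KB assignments into a consensus record."""
    if not assignments:
        raise ValueError("apply_consensus requires at least one assignment")
    gene_ref = assignments[0].gene_ref
    fired = [rid for a in assignments for rid in a.fired_rules]
    fired_set = set(fired)
    tags = rules.tags_of(fired_set)
    by_kb = {a.kb: a.category for a in assignments}

    def record(category: Category, basis: Basis, **kw) -> ConsensusRecord:
        return ConsensusRecord(
            gene_ref=gene_ref, category=category, basis=basis, fired_rules=fired, **kw
        )

    # 1. Exclusion track: pseudogenes/phantom genes are decided first.
    if Category.EXCLUDED in by_kb.values():
        return record(Category.EXCLUDED, Basis.AGREEMENT)
    # 2-5. High-trust exceptions, all implying well_annotated.
    if "ecocyc_evidence" in tags:
        return record(Category.WELL_ANNOTATED, Basis.EXCEPTION_EVIDENCE)
    if "regulondb_strong" in tags:
        return record(Category.WELL_ANNOTATED, Basis.EXCEPTION_REGULONDB)
    if (
        by_kb.get(KnowledgeBase.ECOCYC) is Category.WELL_ANNOTATED
        and by_kb.get(KnowledgeBase.UNIPROT) is Category.WELL_ANNOTATED
    ):
        return record(Category.WELL_ANNOTATED, Basis.EXCEPTION_ECOCYC_UNIPROT)
    if any(".structured.insertion" in rid or rid.endswith(".structured.ins_name")
           for rid in fired_set):
        return record(Category.WELL_ANNOTATED, Basis.EXCEPTION_INSERTION)
    # 6. Agreement among definite votes.
    definite = {c for c in by_kb.values() if c.definite}
    if len(definite) == 1:
        return record(next(iter(definite)), Basis.AGREEMENT)
    if not definite:
        # No KB could place the gene: by definition it lacks evidence.
        return record(Category.YOME, Basis.AGREEMENT, low_confidence=True)
    # 7. Disagreement: manual curation or unresolved.
    if override is not None:
        return record(override.category, Basis.MANUAL)
    return ConsensusRecord(
        gene_ref=gene_ref, category=None, basis=Basis.UNRESOLVED, fired_rules=fired
    )


# ---------------------------------------------------------------------------
# No-information detection

#: Feature types whose text counts as annotation content.
_CONTENT_TYPES = (FeatureType.DESCRIPTION, FeatureType.SUMMARY, FeatureType.EVIDENCE)


def detect_no_info(features: list[KBFeature], phrases: list[str]) -> bool:
    """True iff no knowledge base holds any functional information.

    Every content-bearing feature must be empty, match a stock
    no-information phrase, or be a domain/family-only annotation. Genes
    annotated only with a protein domain still count: such domains (DUFs)
    typically carry no functional information themselves.
    """
    phrases = [p.lower() for p in phrases]
    informative_types = set(_CONTENT_TYPES) | {
        FeatureType.REACTION_EQUATION,
        FeatureType.COMPLEX,
        FeatureType.TF_EVIDENCE,
        FeatureType.ANNOTATION_SCORE,
    }
    for feat in features:
        if feat.feature_type is FeatureType.DOMAIN_ONLY:
            continue
        if feat.feature_type not in informative_types:
            continue
        if feat.feature_type is FeatureType.ANNOTATION_SCORE:
            # A low annotation score is itself a statement of no information.
            if int(feat.value) <= 2:
                continue
            return False
        text = feat.value.strip().lower()
        if not text:
            continue
        if any(p in text for p in phrases):
            continue
        return False
    return True


# ---------------------------------------------------------------------------
# Finalization


@dataclass
class FinalTable:
    """Finalized per-gene categories with bookkeeping counts."""

    records: dict[str, ConsensusRecord]
    category_counts: dict[str, int] = field(default_factory=dict)
    basis_counts: dict[str, int] = field(default_factory=dict)
    no_info_count: int = 0

    def categories(self) -> dict[str, Category]:
        return {g: r.category for g, r in self.records.items()}


def finalize(
    records: dict[str, ConsensusRecord],
    overrides: dict[str, ManualOverride],
    strict: bool = True,
) -> FinalTable:
    """Resolve intermediate consensus records into a full partition.

    Overrides apply to every gene they name: on unresolved genes they supply
    the missing decision; on resolved genes they win over the computed
    category (with a warning) — manual curation is the court of last resort.
    In strict mode any unresolved gene without an override is an error; in
    permissive mode such genes fall into the y-ome flagged low-confidence
    with ``basis=unresolved`` preserved for inspection.
    """
    final: dict[str, ConsensusRecord] = {}
    uncovered: list[str] = []
    for gene_id, rec in records.items():
        override = overrides.get(gene_id)
        if override is not None:
            if rec.basis is not Basis.UNRESOLVED:
                logger.warning(
                    "override on %s replaces computed %s/%s",
                    gene_id, rec.category, rec.basis.value,
                )
            rec = ConsensusRecord(
                gene_ref=gene_id,
                category=override.category,
                basis=Basis.MANUAL,
                fired_rules=rec.fired_rules,
            )
        elif rec.basis is Basis.UNRESOLVED:
            uncovered.append(gene_id)
            rec = ConsensusRecord(
                gene_ref=gene_id,
                category=Category.YOME,
                basis=Basis.UNRESOLVED,
                low_confidence=True,
                fired_rules=rec.fired_rules,
            )
        final[gene_id] = rec
    if uncovered and strict:
        raise UnresolvedGenesError(sorted(uncovered))

    table = FinalTable(records=final)
    for rec in final.values():
        table.category_counts[rec.category.value] = (
            table.category_counts.get(rec.category.value, 0) + 1
        )
        table.basis_counts[rec.basis.value] = (
            table.basis_counts.get(rec.basis.value, 0) + 1
        )
        table.no_info_count += rec.no_info
    assert sum(table.category_counts.values()) == len(final)
    return table


def run_consensus(
    store,
    assignments: dict[str, list[CategoryAssignment]],
    rules: RuleSet,
    overrides: dict[str, ManualOverride] | None = None,
    strict: bool = True,
) -> FinalTable:
    """Consensus + no-info flagging + finalization for a whole store."""
    overrides = overrides or {}
    records: dict[str, ConsensusRecord] = {}
    for gene_id, assigns in assignments.items():
        if not assigns:
            records[gene_id] = ConsensusRecord(
                gene_ref=gene_id,
                category=Category.YOME,
                basis=Basis.AGREEMENT,
                low_confidence=True,
            )
            continue
        # Overrides are applied centrally by finalize(); apply_consensus
        # only computes the automated part here.
        records[gene_id] = apply_consensus(assigns, rules)
    table = finalize(records, overrides, strict=strict)
    # No-information flag: only meaningful inside the y-ome.
    for gene_id, rec in table.records.items():
        if rec.category is Category.YOME and detect_no_info(
            store.features_for(gene_id), rules.no_info_phrases
        ):
            rec.no_info = True
    table.no_info_count = sum(r.no_info for r in table.records.values())
    return table


# ---------------------------------------------------------------------------
# I/O for the override and category tables

import pandas as pd  # noqa: E402


def read_overrides(path) -> dict[str, ManualOverride]:
    """Read the manual-override TSV (gene_id, category, justification, curator, date)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    overrides = {}
    for row in df.itertuples(index=False):
        overrides[row.gene_id] = ManualOverride(
            gene_ref=row.gene_id,
            category=Category(row.category),
            justification=row.justification,
            curator=getattr(row, "curator", ""),
            date=getattr(row, "date", ""),
        )
    return overrides


def write_category_table(table: FinalTable, store, path) -> pd.DataFrame:
    """Write the final category TSV (one row per registry gene)."""
    rows = []
    for gene_id in sorted(table.records):
        rec = table.records[gene_id]
        rows.append(
            {
                "gene_id": gene_id,
                "primary_name": store.genes[gene_id].primary_name,
                "category": rec.category.value,
                "basis": rec.basis.value,
                "no_info": rec.no_info,
                "fired_rules": ";".join(rec.fired_rules),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "primary_name", "category", "basis", "no_info", "fired_rules"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_category_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "primary_name": str})
    required = {"gene_id", "primary_name", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: category table missing columns {sorted(missing)}")
    bad = set(df["category"]) - {c.value for c in FINAL_CATEGORIES}
    if bad:
        raise ValueError(f"{path}: unknown categories {sorted(bad)}")
    return df
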