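"""Core domain types shared across the pipeline.

The pipeline resolves a registry of unique genes across several knowledge
bases (KBs), attaches per-KB annotation *features* to them, categorizes each
gene per KB, and finally assigns one of three consensus categories:

* ``yome`` — no experimental evidence of function with a mechanistic link to
  phenotype,
* ``well_annotated`` — sufficient functional evidence,
* ``excluded`` — pseudogenes and phantom genes, kept out of the y-ome.

A fourth per-KB-only state, ``insufficient``, marks genes a single knowledge
base cannot place ("not enough information for automated assignment").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class KnowledgeBase(str, enum.Enum):
    """Supported annotation sources."""

    ECOCYC = "ecocyc"
    ECOGENE = "ecogene"
    UNIPROT = "uniprot"
    REGULONDB = "regulondb"
    REFSEQ = "refseq"


#: Knowledge bases whose assignments participate in categorization by
#: default. RefSeq features are ingested for comparison only.
CATEGORIZATION_KBS: tuple[KnowledgeBase, ...] = (
    KnowledgeBase.ECOCYC,
    KnowledgeBase.ECOGENE,
    KnowledgeBase.UNIPROT,
    KnowledgeBase.REGULONDB,
)


class FeatureType(str, enum.Enum):
    DESCRIPTION = "description"
    SUMMARY = "summary"
    EVIDENCE = "evidence"
    ANNOTATION_SCORE = "annotation_score"
    REACTION_EQUATION = "reaction_equation"
    COMPLEX = "complex"
    TF_EVIDENCE = "tf_evidence"
    PSEUDOGENE_FLAG = "pseudogene_flag"
    PHANTOM_FLAG = "phantom_flag"
    INSERTION_FLAG = "insertion_flag"
    DOMAIN_ONLY = "domain_only"
    OTHER = "other"


class Category(str, enum.Enum):
    """Annotation level of a gene, per KB or in consensus."""

    YOME = "yome"
    WELL_ANNOTATED = "well_annotated"
    INSUFFICIENT = "insufficient"
    EXCLUDED = "excluded"

    @property
    def definite(self) -> bool:
        """A definite category is an actual vote (not ``insufficient``)."""
        return self is not Category.INSUFFICIENT


#: Final (consensus) categories — ``insufficient`` never survives consensus.
FINAL_CATEGORIES: tuple[Category, ...] = (
    Category.YOME,
    Category.WELL_ANNOTATED,
    Category.EXCLUDED,
)


class Basis(str, enum.Enum):
    """Which consensus rule decided a gene's final category."""

    AGREEMENT = "agreement"
    EXCEPTION_EVIDENCE = "exception_evidence"
    EXCEPTION_REGULONDB = "exception_regulondb"
    EXCEPTION_ECOCYC_UNIPROT = "exception_ecocyc_uniprot"
    EXCEPTION_INSERTION = "exception_insertion"
    MANUAL = "manual"
    UNRESOLVED = "unresolved"


@dataclass
class GeneRecord:
    """One unique gene resolved across knowledge bases.

    ``gene_id`` is the locus tag (b-number) when any source provides one,
    otherwise a generated surrogate identifier.
    """

    gene_id: str
    primary_name: str
    synonyms: set[str] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.primary_name:
            raise ValueError(f"gene {self.gene_id!r}: primary_name must be non-empty")

    def all_names(self) -> set[str]:
        return {self.primary_name} | self.synonyms


@dataclass(frozen=True)
class KBFeature:
    """One text or structured annotation attached to a gene by one KB."""

    gene_ref: str
    kb: KnowledgeBase
    feature_type: FeatureType
    value: str

    def __post_init__(self) -> None:
        if self.feature_type is FeatureType.ANNOTATION_SCORE:
            try:
                score = int(self.value)
            except ValueError:
                raise ValueError(
                    f"annotation_score value {self.value!r} is not an integer"
                ) from None
            if not 1 <= score <= 5:
                raise ValueError(f"annotation_score {score} outside 1-5")


@dataclass
class CategoryAssignment:
    """Per-knowledge-base category for a gene with the rules that fired."""

    gene_ref: str
    kb: KnowledgeBase
    category: Category
    fired_rules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category is not Category.INSUFFICIENT and not self.fired_rules:
            raise ValueError(
                f"{self.gene_ref}/{self.kb.value}: a definite category requires "
                "at least one fired rule"
            )


@dataclass
class ConsensusRecord:
    """Final category for a gene, with the rule that decided it.

    ``basis=unresolved`` (category ``None``) appears only in intermediate
    output; :func:`yome.consensus.finalize` removes or rejects it.
    ``no_info`` marks y-ome genes for which no functional information at all
    exists in any knowledge base; it implies ``category=yome``.
    """

    gene_ref: str
    category: Category | None
    basis: Basis
    no_info: bool = False
    low_confidence: bool = False
    fired_rules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.no_info and self.category is not Category.YOME:
            raise ValueError("no_info implies category=yome")
        if self.category is None and self.basis is not Basis.UNRESOLVED:
            raise ValueError("missing category only allowed with basis=unresolved")


@dataclass(frozen=True)
class ManualOverride:
    """A curator's decision for one gene, applied where consensus fails."""

    gene_ref: str
    category: Category
    justification: str
    curator: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        if not self.justification:
            raise ValueError(f"override for {self.gene_ref}: justification required")
        if self.category not in FINAL_CATEGORIES:
            raise ValueError(f"override for {self.gene_ref}: category must be final")
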