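"""Per-knowledge-base gene categorization.

Two kinds of rules assign a category to a gene within one knowledge base:

* **keyword rules** — case-insensitive pattern matches against a single
  feature's text (substring by default, word-boundary mode per rule);
* **structured rules** — fire on structured annotations of the gene's whole
  per-KB feature set: reaction equations, complex membership and insertion
  elements imply ``well_annotated``; pseudogene/phantom flags and EcoGene's
  apostrophe naming convention imply ``excluded``; a UniProt annotation score
  of 1-2 implies ``yome``, 3 ``insufficient`` and 4-5 ``well_annotated``.

When several rules fire for one gene in one KB the category is resolved by
the precedence ``excluded > well_annotated > yome``; no fired rule means
``insufficient``. Cryptic (phenotypically silent) genes receive no special
rule: they remain in the y-ome.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import (
    Category,
    CategoryAssignment,
    FeatureType,
    KBFeature,
    KnowledgeBase,
)

#: Within-KB precedence for conflicting fired rules (highest first).
CATEGORY_PRECEDENCE = (
    Category.EXCLUDED,
    Category.WELL_ANNOTATED,
    Category.YOME,
)


@dataclass(frozen=True)
class KeywordRule:
    kb: KnowledgeBase
    feature_type: FeatureType
    pattern: str
    target: Category
    match_mode: str = "substring"  # or "word"
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("keyword rule pattern must be non-empty")
        object.__setattr__(self, "pattern", self.pattern.lower())
        if self.match_mode not in ("substring", "word"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")

    @property
    def rule_id(self) -> str:
        return f"{self.kb.value}.{self.feature_type.value}.{self.pattern}"

    def matches(self, text: str) -> bool:
        text = text.lower()
        if self.match_mode == "substring":
            return self.pattern in text
        return re.search(rf"\b{re.escape(self.pattern)}\b", text) is not None


@dataclass
class RuleSet:
    keyword_rules: list[KeywordRule] = field(default_factory=list)
    structured: dict[str, bool] = field(default_factory=dict)
    no_info_phrases: list[str] = field(default_factory=list)

    def rules_for(self, kb: KnowledgeBase, ftype: FeatureType) -> list[KeywordRule]:
        return [
            r for r in self.keyword_rules if r.kb == kb and r.feature_type == ftype
        ]

    def tags_of(self, rule_ids: set[str]) -> set[str]:
        return {r.tag for r in self.keyword_rules if r.tag and r.rule_id in rule_ids}


def load_rules(path: str | Path | None = None) -> RuleSet:
    """Load a rule set from YAML; with no path, load the shipped defaults."""
    if path is None:
        text = (
            importlib.resources.files("yome.data")
            .joinpath("default_rules.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    rules = [
        KeywordRule(
            kb=KnowledgeBase(r["kb"]),
            feature_type=FeatureType(r["feature_type"]),
            pattern=str(r["pattern"]),
            target=Category(r["target"]),
            match_mode=r.get("match_mode", "substring"),
            tag=r.get("tag", ""),
        )
        for r in raw.get("keyword_rules", [])
    ]
    return RuleSet(
        keyword_rules=rules,
        structured=dict(raw.get("structured_rules", {})),
        no_info_phrases=[p.lower() for p in raw.get("no_info_phrases", [])],
    )


def classify_feature(
    feature: KBFeature, rules: RuleSet
) -> list[tuple[Category, str]]:
    """Apply every keyword rule of the feature's KB/type; return all matches."""
    return [
        (rule.target, rule.rule_id)
        for rule in rules.rules_for(feature.kb, feature.feature_type)
        if rule.matches(feature.value)
    ]


def uniprot_score_rule(score: int) -> Category:
    """Map a UniProt annotation score (1-5) to a category.

    Scores of two or below indicate the y-ome, four or above well-annotated;
    a score of three carries not enough information for automated assignment.
    """
    if not isinstance(score, int) or not 1 <= score <= 5:
        raise ValueError(f"annotation score must be an integer in 1..5, got {score!r}")
    if score <= 2:
        return Category.YOME
    if score >= 4:
        return Category.WELL_ANNOTATED
    return Category.INSUFFICIENT


def structured_rules(
    features: list[KBFeature],
    rules: RuleSet,
    primary_name: str = "",
) -> list[tuple[Category, str]]:
    """Apply structured-data rules to one gene's features within one KB."""
    if not features:
        return []
    kb = features[0].kb
    on = rules.structured.get
    fired: list[tuple[Category, str]] = []
    for feat in features:
        ft = feat.feature_type
        if ft is FeatureType.REACTION_EQUATION and on("reaction_equation_well_annotated", True):
            fired.append((Category.WELL_ANNOTATED, f"{kb.value}.structured.reaction_equation"))
        elif ft is FeatureType.COMPLEX and on("complex_well_annotated", True):
            fired.append((Category.WELL_ANNOTATED, f"{kb.value}.structured.complex"))
        elif ft is FeatureType.INSERTION_FLAG and on("insertion_well_annotated", True):
            fired.append((Category.WELL_ANNOTATED, f"{kb.value}.structured.insertion"))
        elif ft is FeatureType.PSEUDOGENE_FLAG and on("pseudogene_excluded", True):
            fired.append((Category.EXCLUDED, f"{kb.value}.structured.pseudogene"))
        elif ft is FeatureType.PHANTOM_FLAG and on("phantom_excluded", True):
            fired.append((Category.EXCLUDED, f"{kb.value}.structured.phantom"))
        elif ft is FeatureType.ANNOTATION_SCORE and kb is KnowledgeBase.UNIPROT:
            cat = uniprot_score_rule(int(feat.value))
            if cat.definite:
                fired.append((cat, f"uniprot.structured.annotation_score_{feat.value}"))
    if (
        kb is KnowledgeBase.ECOGENE
        and primary_name.endswith("'")
        and on("ecogene_apostrophe_excluded", True)
    ):
        fired.append((Category.EXCLUDED, "ecogene.structured.apostrophe_name"))
    if (
        kb is KnowledgeBase.ECOCYC
        and primary_name.lower().startswith("ins")
        and on("insertion_well_annotated", True)
    ):
        fired.append((Category.WELL_ANNOTATED, "ecocyc.structured.ins_name"))
    return fired


def resolve_precedence(fired: list[tuple[Category, str]]) -> Category:
    """Collapse fired rules to one category by within-KB precedence."""
    cats = {cat for cat, _ in fired}
    for cat in CATEGORY_PRECEDENCE:
        if cat in cats:
            return cat
    return Category.INSUFFICIENT


def classify_gene_kb(
    gene_ref: str,
    features: list[KBFeature],
    rules: RuleSet,
    primary_name: str = "",
) -> CategoryAssignment:
    """Categorize one gene within one knowledge base.

    All fired rules (keyword and structured) are recorded; the category is
    the highest-precedence target among them, or ``insufficient`` when
    nothing fired.
    """
    kb = features[0].kb if features else None
    fired: list[tuple[Category, str]] = []
    for feat in features:
        fired.extend(classify_feature(feat, rules))
    fired.extend(structured_rules(features, rules, primary_name))
    category = resolve_precedence(fired)
    return CategoryAssignment(
        gene_ref=gene_ref,
        kb=kb if kb is not None else KnowledgeBase.ECOCYC,
        category=category,
        fired_rules=[rid for _, rid in fired],
    )


def classify_store(store, rules: RuleSet, kbs=None) -> dict[str, list[CategoryAssignment]]:
    """Categorize every registry gene in every categorization KB it appears in.

    RefSeq is ingested for comparison only and excluded unless listed in
    ``kbs`` explicitly.
    """
    from .types import CATEGORIZATION_KBS

    kbs = tuple(kbs) if kbs is not None else CATEGORIZATION_KBS
    by_gene_kb: dict[tuple[str, KnowledgeBase], list[KBFeature]] = {}
    for feat in store.features:
        by_gene_kb.setdefault((feat.gene_ref, feat.kb), []).append(feat)
    assignments: dict[str, list[CategoryAssignment]] = {g: [] for g in store.genes}
    for (gene_id, kb), feats in sorted(
        by_gene_kb.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        if kb not in kbs:
            continue
        rec = store.genes[gene_id]
        assignments[gene_id].append(
            classify_gene_kb(gene_id, feats, rules, primary_name=rec.primary_name)
        )
    return assignments
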