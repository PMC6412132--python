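"""Consensus rules, exception heuristics, no-info detection, finalization."""

from __future__ import annotations

import itertools

import pytest

from yome.categorize import load_rules
from yome.consensus import (
    UnresolvedGenesError,
    apply_consensus,
    detect_no_info,
    finalize,
)
from yome.types import (
    Basis,
    Category,
    CategoryAssignment,
    ConsensusRecord,
    FeatureType,
    KBFeature,
    KnowledgeBase,
    ManualOverride,
)

KBS = (
    KnowledgeBase.ECOCYC,
    KnowledgeBase.ECOGENE,
    KnowledgeBase.UNIPROT,
    KnowledgeBase.REGULONDB,
)
STATES = ("well", "yome", "insufficient", "excluded", "absent")
_CAT = {
    "well": Category.WELL_ANNOTATED,
    "yome": Category.YOME,
    "insufficient": Category.INSUFFICIENT,
    "excluded": Category.EXCLUDED,
}


def assignment(kb: KnowledgeBase, state: str) -> CategoryAssignment:
    cat = _CAT[state]
    fired = [] if cat is Category.INSUFFICIENT else [f"{kb.value}.generic.{state}"]
    return CategoryAssignment(gene_ref="b1", kb=kb, category=cat, fired_rules=fired)


def oracle(states: dict[KnowledgeBase, str], has_override: bool):
    """Plain-enumeration restatement of the consensus procedure.

    Generic assignments only: none of the feature-level exception tags
    (curated evidence, strong TF evidence, insertion elements) are present,
    so only the exclusion rule, the EcoCyc+UniProt exception, agreement and
    the disagreement fallback can apply.
    """
    cats = {kb: _CAT[s] for kb, s in states.items() if s != "absent"}
    if Category.EXCLUDED in cats.values():
        return Category.EXCLUDED, Basis.AGREEMENT
    if (
        cats.get(KnowledgeBase.ECOCYC) is Category.WELL_ANNOTATED
        and cats.get(KnowledgeBase.UNIPROT) is Category.WELL_ANNOTATED
    ):
        return Category.WELL_ANNOTATED, Basis.EXCEPTION_ECOCYC_UNIPROT
    definite = [c for c in cats.values() if c is not Category.INSUFFICIENT]
    if definite and all(c is definite[0] for c in definite):
        return definite[0], Basis.AGREEMENT
    if not definite:
        return Category.YOME, Basis.AGREEMENT
    if has_override:
        return Category.WELL_ANNOTATED, Basis.MANUAL  # oracle override target
    return None, Basis.UNRESOLVED


@pytest.mark.parametrize("has_override", [False, True])
def test_exhaustive_oracle_over_all_kb_state_combinations(default_rules, has_override):
    """apply_consensus matches the independent oracle on all 5^4 combos."""
    override = ManualOverride("b1", Category.WELL_ANNOTATED, "curated") if has_override else None
    n_checked = 0
    for combo in itertools.product(STATES, repeat=len(KBS)):
        states = dict(zip(KBS, combo))
        assignments = [
            assignment(kb, s) for kb, s in states.items() if s != "absent"
        ]
        if not assignments:
            continue  # apply_consensus requires at least one assignment
        rec = apply_consensus(assignments, default_rules, override=override)
        want_cat, want_basis = oracle(states, has_override)
        assert rec.category is want_cat, (states, rec)
        assert rec.basis is want_basis, (states, rec)
        n_checked += 1
    assert n_checked == 5**4 - 1


class TestExceptions:
    def make(self, kb, state):
        return assignment(KnowledgeBase(kb), state)

    def test_agreement_with_insufficient_others(self, default_rules):
        rec = apply_consensus(
            [self.make("ecocyc", "well"), self.make("ecogene", "insufficient"),
             self.make("uniprot", "insufficient")],
            default_rules,
        )
        assert (rec.category, rec.basis) == (Category.WELL_ANNOTATED, Basis.AGREEMENT)

    def test_ecocyc_uniprot_both_well_beats_dissent(self, default_rules):
        rec = apply_consensus(
            [self.make("ecocyc", "well"), self.make("uniprot", "well"),
             self.make("ecogene", "yome")],
            default_rules,
        )
        assert (rec.category, rec.basis) == (
            Category.WELL_ANNOTATED, Basis.EXCEPTION_ECOCYC_UNIPROT,
        )

    def test_disagreement_without_override_is_unresolved(self, default_rules):
        rec = apply_consensus(
            [self.make("ecocyc", "yome"), self.make("ecogene", "well")], default_rules
        )
        assert rec.basis is Basis.UNRESOLVED and rec.category is None

    def test_regulondb_strong_evidence_wins(self, default_rules):
        strong = CategoryAssignment(
            gene_ref="b1",
            kb=KnowledgeBase.REGULONDB,
            category=Category.WELL_ANNOTATED,
            fired_rules=["regulondb.tf_evidence.strong"],
        )
        rec = apply_consensus(
            [strong, self.make("ecocyc", "yome")], default_rules
        )
        assert (rec.category, rec.basis) == (
            Category.WELL_ANNOTATED, Basis.EXCEPTION_REGULONDB,
        )

    def test_ecocyc_evidence_overrides_ecocyc_yome_keyword(self, default_rules):
        mixed = CategoryAssignment(
            gene_ref="b1",
            kb=KnowledgeBase.ECOCYC,
            category=Category.WELL_ANNOTATED,  # within-KB precedence outcome
            fired_rules=["ecocyc.description.predicted", "ecocyc.evidence.assay"],
        )
        rec = apply_consensus([mixed], default_rules)
        assert (rec.category, rec.basis) == (
            Category.WELL_ANNOTATED, Basis.EXCEPTION_EVIDENCE,
        )

    def test_exclusion_beats_every_evidence_exception(self, default_rules):
        evidence = CategoryAssignment(
            gene_ref="b1",
            kb=KnowledgeBase.ECOCYC,
            category=Category.WELL_ANNOTATED,
            fired_rules=["ecocyc.evidence.assay"],
        )
        rec = apply_consensus(
            [evidence, self.make("ecogene", "excluded")], default_rules
        )
        assert rec.category is Category.EXCLUDED

    def test_all_insufficient_defaults_to_yome_low_confidence(self, default_rules):
        rec = apply_consensus(
            [self.make("ecocyc", "insufficient"), self.make("uniprot", "insufficient")],
            default_rules,
        )
        assert rec.category is Category.YOME and rec.low_confidence

    def test_exception_order_cannot_change_the_category(self, default_rules):
        """Exceptions 2-5 all output well_annotated: any serialization of
        the deciding signals yields the same category."""
        signals = {
            "evidence": CategoryAssignment(
                "b1", KnowledgeBase.ECOCYC, Category.WELL_ANNOTATED,
                ["ecocyc.evidence.assay"],
            ),
            "regulondb": CategoryAssignment(
                "b1", KnowledgeBase.REGULONDB, Category.WELL_ANNOTATED,
                ["regulondb.tf_evidence.strong"],
            ),
            "uniprot_well": CategoryAssignment(
                "b1", KnowledgeBase.UNIPROT, Category.WELL_ANNOTATED,
                ["uniprot.structured.annotation_score_5"],
            ),
            "insertion": CategoryAssignment(
                "b1", KnowledgeBase.ECOGENE, Category.WELL_ANNOTATED,
                ["ecogene.structured.insertion"],
            ),
        }
        for perm in itertools.permutations(signals.values()):
            rec = apply_consensus(list(perm), default_rules)
            assert rec.category is Category.WELL_ANNOTATED


class TestDetectNoInfo:
    phrases = load_rules().no_info_phrases

    def feat(self, kb, ftype, value):
        return KBFeature("b1", KnowledgeBase(kb), FeatureType(ftype), value)

    def test_stock_summary_phrase(self):
        feats = [self.feat("ecocyc", "summary",
                           "No information about this protein was found by a "
                           "literature search conducted on 23 February 2017")]
        assert detect_no_info(feats, self.phrases)

    def test_putative_uncharacterized(self):
        assert detect_no_info(
            [self.feat("uniprot", "description", "Putative uncharacterized protein")],
            self.phrases,
        )

    def test_domain_only_annotation_still_no_info(self):
        assert detect_no_info(
            [self.feat("uniprot", "domain_only", "DUF1479")], self.phrases
        )

    def test_real_description_is_informative(self):
        assert not detect_no_info(
            [self.feat("ecocyc", "description", "ATP synthase subunit"),
             self.feat("ecocyc", "summary", "No information about this gene")],
            self.phrases,
        )

    def test_empty_features_count_as_no_info(self):
        assert detect_no_info([self.feat("ecocyc", "description", "")], self.phrases)


class TestFinalize:
    def unresolved(self, gid):
        return ConsensusRecord(gene_ref=gid, category=None, basis=Basis.UNRESOLVED)

    def resolved(self, gid, cat=Category.WELL_ANNOTATED):
        return ConsensusRecord(gene_ref=gid, category=cat, basis=Basis.AGREEMENT)

    def test_override_completes_the_partition(self):
        records = {"b1": self.resolved("b1"), "b2": self.unresolved("b2")}
        overrides = {"b2": ManualOverride("b2", Category.YOME, "curated")}
        table = finalize(records, overrides, strict=True)
        assert table.records["b2"].category is Category.YOME
        assert table.records["b2"].basis is Basis.MANUAL
        assert sum(table.category_counts.values()) == 2

    def test_override_on_resolved_gene_wins_with_manual_basis(self):
        records = {"b1": self.resolved("b1", Category.WELL_ANNOTATED)}
        overrides = {"b1": ManualOverride("b1", Category.YOME, "curator disagrees")}
        table = finalize(records, overrides)
        assert table.records["b1"].category is Category.YOME
        assert table.records["b1"].basis is Basis.MANUAL

    def test_strict_mode_names_the_unresolved_gene(self):
        records = {"b7": self.unresolved("b7")}
        with pytest.raises(UnresolvedGenesError, match="b7"):
            finalize(records, {}, strict=True)

    def test_permissive_mode_flags_and_passes_through(self):
        records = {"b7": self.unresolved("b7")}
        table = finalize(records, {}, strict=False)
        rec = table.records["b7"]
        assert rec.category is Category.YOME and rec.low_confidence
        assert rec.basis is Basis.UNRESOLVED


def test_partition_and_no_info_subset_on_generated_suite(small_suite):
    _, labels, table, _ = small_suite
    cats = [r.category for r in table.records.values()]
    assert all(c in (Category.YOME, Category.WELL_ANNOTATED, Category.EXCLUDED) for c in cats)
    assert len(table.records) == len(labels)
    for rec in table.records.values():
        if rec.no_info:
            assert rec.category is Category.YOME
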