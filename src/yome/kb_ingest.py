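"""Ingest knowledge-base dumps into a normalized feature store.

Each knowledge base is delivered to the pipeline as a canonical TSV *feature
table* (one annotation per row); adapters for native dump formats are thin
translators that emit this format. Ingestion resolves a unique-gene registry
across sources: fragments sharing a locus tag merge first, then fragments
without a locus tag merge by exact primary-name or synonym match — locus tags
are the only stable cross-KB key.

Feature values are preserved verbatim (no case folding); categorization rules
handle case downstream.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

from .types import FeatureType, GeneRecord, KBFeature, KnowledgeBase

logger = logging.getLogger(__name__)

#: Header of the canonical feature-table TSV.
FEATURE_TABLE_COLUMNS = (
    "kb",
    "locus_tag",
    "primary_name",
    "synonyms",
    "feature_type",
    "feature_value",
)


class SchemaError(ValueError):
    """The feature-table header does not match the canonical schema."""


@dataclass(frozen=True)
class GeneFragment:
    """Gene identity information carried by one feature-table row."""

    kb: KnowledgeBase
    locus_tag: str | None
    primary_name: str
    synonyms: frozenset[str] = frozenset()


@dataclass
class RowError:
    line: int
    message: str


@dataclass
class ParseResult:
    rows: list[tuple[GeneFragment, KBFeature]]
    errors: list[RowError]


@dataclass
class FeatureStore:
    """Registry of unique genes plus every ingested annotation feature."""

    genes: dict[str, GeneRecord] = field(default_factory=dict)
    features: list[KBFeature] = field(default_factory=list)
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)

    def validate(self) -> None:
        missing = {f.gene_ref for f in self.features} - set(self.genes)
        if missing:
            raise ValueError(f"features reference unknown genes: {sorted(missing)[:5]}")

    def features_for(
        self, gene_id: str, kb: KnowledgeBase | None = None
    ) -> list[KBFeature]:
        return [
            f
            for f in self.features
            if f.gene_ref == gene_id and (kb is None or f.kb == kb)
        ]


def parse_feature_table(path: str | Path, kb: str | KnowledgeBase) -> ParseResult:
    """Parse one canonical feature-table TSV for one knowledge base.

    Returns one ``(GeneFragment, KBFeature)`` per well-formed data row.
    Malformed rows are collected as :class:`RowError` with 1-based line
    numbers and skipped; a wrong header raises :class:`SchemaError`.

    The ``gene_ref`` on the returned features is provisional (locus tag, or
    the primary name for rows without one); :func:`build_registry` and
    :func:`assemble_store` remap it to the final registry identifier.
    """
    kb = KnowledgeBase(kb)
    path = Path(path)
    rows: list[tuple[GeneFragment, KBFeature]] = []
    errors: list[RowError] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != FEATURE_TABLE_COLUMNS:
            raise SchemaError(
                f"{path}: header {header} does not match canonical schema "
                f"{list(FEATURE_TABLE_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(FEATURE_TABLE_COLUMNS):
                errors.append(RowError(lineno, f"expected 6 fields, got {len(parts)}"))
                continue
            row_kb, locus_tag, primary_name, synonyms, ftype, fvalue = parts
            if row_kb != kb.value:
                errors.append(RowError(lineno, f"kb {row_kb!r} != expected {kb.value!r}"))
                continue
            if not locus_tag and not primary_name:
                errors.append(RowError(lineno, "row has neither locus_tag nor primary_name"))
                continue
            try:
                feature_type = FeatureType(ftype)
            except ValueError:
                errors.append(RowError(lineno, f"unknown feature_type {ftype!r}"))
                continue
            fragment = GeneFragment(
                kb=kb,
                locus_tag=locus_tag or None,
                primary_name=primary_name or locus_tag,
                synonyms=frozenset(s for s in synonyms.split("|") if s),
            )
            gene_ref = fragment.locus_tag or fragment.primary_name
            try:
                feature = KBFeature(gene_ref, kb, feature_type, fvalue)
            except ValueError as exc:
                errors.append(RowError(lineno, str(exc)))
                continue
            rows.append((fragment, feature))
    for err in errors:
        logger.warning("%s:%d: %s", path, err.line, err.message)
    return ParseResult(rows=rows, errors=errors)


def build_registry(fragments: list[GeneFragment]) -> dict[str, GeneRecord]:
    """Resolve gene fragments from all KBs into a registry of unique genes.

    Merge precedence: shared locus tag, then exact primary-name match, then
    synonym match. Conflicting primary names under one locus tag keep the
    first-seen name as primary and demote the rest to synonyms (the locus tag
    wins as identity).
    """
    registry: dict[str, GeneRecord] = {}
    by_locus: dict[str, str] = {}
    by_name: dict[str, str] = {}  # lowercase name/synonym -> gene_id
    surrogate_counter = 0

    def index_names(rec: GeneRecord) -> None:
        for name in rec.all_names():
            by_name.setdefault(name.lower(), rec.gene_id)

    for frag in fragments:
        gene_id: str | None = None
        if frag.locus_tag and frag.locus_tag in by_locus:
            gene_id = by_locus[frag.locus_tag]
        if gene_id is None:
            for name in {frag.primary_name, *frag.synonyms}:
                if name.lower() in by_name:
                    gene_id = by_name[name.lower()]
                    break
        if gene_id is None:
            if frag.locus_tag:
                gene_id = frag.locus_tag
            else:
                surrogate_counter += 1
                gene_id = f"surr{surrogate_counter:05d}"
            registry[gene_id] = GeneRecord(
                gene_id=gene_id,
                primary_name=frag.primary_name,
                synonyms=set(frag.synonyms),
                sources={frag.kb.value},
            )
            if frag.locus_tag:
                by_locus[frag.locus_tag] = gene_id
            index_names(registry[gene_id])
            continue

        rec = registry[gene_id]
        if frag.locus_tag and gene_id.startswith("surr"):
            # A later source supplies the locus tag for a surrogate gene:
            # keep the surrogate id stable but index the tag.
            by_locus.setdefault(frag.locus_tag, gene_id)
        if (
            frag.primary_name
            and frag.primary_name != rec.primary_name
            and frag.locus_tag == gene_id
        ):
            logger.warning(
                "locus tag %s: conflicting primary names %r / %r; keeping %r",
                gene_id,
                rec.primary_name,
                frag.primary_name,
                rec.primary_name,
            )
        if frag.primary_name and frag.primary_name != rec.primary_name:
            rec.synonyms.add(frag.primary_name)
        rec.synonyms |= set(frag.synonyms) - {rec.primary_name}
        rec.sources.add(frag.kb.value)
        index_names(rec)
    return registry


def assemble_store(
    parse_results: dict[str, ParseResult],
    provenance: dict[str, tuple[str, str]] | None = None,
) -> FeatureStore:
    """Build a :class:`FeatureStore` from per-KB parse results.

    ``parse_results`` maps kb name to :class:`ParseResult`; features are
    remapped onto the merged registry identifiers.
    """
    all_fragments = [frag for res in parse_results.values() for frag, _ in res.rows]
    registry = build_registry(all_fragments)
    lookup: dict[str, str] = {}
    for rec in registry.values():
        lookup[rec.gene_id] = rec.gene_id
        for name in rec.all_names():
            lookup.setdefault(name.lower(), rec.gene_id)
    features: list[KBFeature] = []
    for res in parse_results.values():
        for frag, feat in res.rows:
            key = frag.locus_tag if frag.locus_tag else frag.primary_name.lower()
            gene_id = lookup.get(key) or lookup[frag.primary_name.lower()]
            features.append(KBFeature(gene_id, feat.kb, feat.feature_type, feat.value))
    store = FeatureStore(
        genes=registry, features=features, provenance=dict(provenance or {})
    )
    store.validate()
    return store


def load_feature_store(
    paths: dict[str, str | Path], versions: dict[str, str] | None = None
) -> tuple[FeatureStore, dict[str, list[RowError]]]:
    """Parse one feature table per KB and assemble the store."""
    results: dict[str, ParseResult] = {}
    errors: dict[str, list[RowError]] = {}
    provenance: dict[str, tuple[str, str]] = {}
    for kb_name, path in paths.items():
        res = parse_feature_table(path, kb_name)
        results[kb_name] = res
        if res.errors:
            errors[kb_name] = res.errors
        provenance[kb_name] = (str(path), (versions or {}).get(kb_name, ""))
    return assemble_store(results, provenance), errors


# ---------------------------------------------------------------------------
# Relational (SQLite) persistence


def save_store(store: FeatureStore, path: str | Path) -> None:
    """Persist the store to a single-file SQLite database."""
    con = sqlite3.connect(path)
    try:
        con.executescript(
            """
            DROP TABLE IF EXISTS genes;
            DROP TABLE IF EXISTS features;
            DROP TABLE IF EXISTS provenance;
            CREATE TABLE genes (
                gene_id TEXT PRIMARY KEY, primary_name TEXT NOT NULL,
                synonyms TEXT, sources TEXT NOT NULL);
            CREATE TABLE features (
                gene_ref TEXT NOT NULL REFERENCES genes(gene_id),
                kb TEXT NOT NULL, feature_type TEXT NOT NULL, value TEXT);
            CREATE TABLE provenance (
                kb TEXT PRIMARY KEY, source_path TEXT, version TEXT);
            """
        )
        con.executemany(
            "INSERT INTO genes VALUES (?,?,?,?)",
            [
                (g.gene_id, g.primary_name, "|".join(sorted(g.synonyms)),
                 "|".join(sorted(g.sources)))
                for g in store.genes.values()
            ],
        )
        con.executemany(
            "INSERT INTO features VALUES (?,?,?,?)",
            [(f.gene_ref, f.kb.value, f.feature_type.value, f.value)
             for f in store.features],
        )
        con.executemany(
            "INSERT INTO provenance VALUES (?,?,?)",
            [(kb, src, ver) for kb, (src, ver) in store.provenance.items()],
        )
        con.commit()
    finally:
        con.close()


def load_store(path: str | Path) -> FeatureStore:
    """Load a store previously written by :func:`save_store`."""
    con = sqlite3.connect(path)
    try:
        genes = {
            gene_id: GeneRecord(
                gene_id=gene_id,
                primary_name=name,
                synonyms=set(s for s in syn.split("|") if s),
                sources=set(src.split("|")),
            )
            for gene_id, name, syn, src in con.execute("SELECT * FROM genes")
        }
        features = [
            KBFeature(ref, KnowledgeBase(kb), FeatureType(ft), val or "")
            for ref, kb, ft, val in con.execute("SELECT * FROM features")
        ]
        provenance = {
            kb: (src, ver) for kb, src, ver in con.execute("SELECT * FROM provenance")
        }
    finally:
        con.close()
    store = FeatureStore(genes=genes, features=features, provenance=provenance)
    store.validate()
    return store


# ---------------------------------------------------------------------------
# Genome annotation (gene start positions)


@dataclass
class PositionReport:
    positions: dict[str, int]
    genome_length: int
    unmatched: list[str]


def load_positions(
    path: str | Path, registry: dict[str, GeneRecord]
) -> PositionReport:
    """Extract gene start sites from a GenBank or GFF3 genome annotation.

    Coordinates are 1-based inclusive on the forward-numbered circular
    chromosome; only start sites are used, so strand is ignored. Genes in the
    registry absent from the annotation are listed in the gap report.
    """
    path = Path(path)
    if path.suffix.lower() in {".gb", ".gbk", ".gbff", ".genbank"}:
        starts, genome_length = _starts_from_genbank(path)
    else:
        starts, genome_length = _starts_from_gff3(path)

    lookup: dict[str, str] = {}
    for rec in registry.values():
        lookup[rec.gene_id.lower()] = rec.gene_id
        for name in rec.all_names():
            lookup.setdefault(name.lower(), rec.gene_id)

    positions: dict[str, int] = {}
    for key, start in starts.items():
        gene_id = lookup.get(key.lower())
        if gene_id is None:
            continue
        if not 1 <= start <= genome_length:
            raise ValueError(
                f"gene {gene_id}: start {start} outside 1..{genome_length}"
            )
        positions.setdefault(gene_id, start)
    if not positions:
        raise ValueError(
            f"{path}: no annotation identifiers matched the registry "
            "(identifier namespace mismatch?)"
        )
    unmatched = sorted(set(registry) - set(positions))
    return PositionReport(positions, genome_length, unmatched)


def _starts_from_genbank(path: Path) -> tuple[dict[str, int], int]:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "genbank"))
    starts: dict[str, int] = {}
    for feat in record.features:
        if feat.type != "gene":
            continue
        start = int(feat.location.start) + 1  # Biopython is 0-based
        for qual in ("locus_tag", "gene"):
            for name in feat.qualifiers.get(qual, []):
                starts.setdefault(name, start)
    return starts, len(record.seq)


def _starts_from_gff3(path: Path) -> tuple[dict[str, int], int]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genome_length = 0
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            genome_length = int(directive.split()[-1])
    if genome_length == 0:
        raise ValueError(f"{path}: GFF3 lacks a ##sequence-region directive")
    starts: dict[str, int] = {}
    for feat in db.features_of_type("gene"):
        for key in ("locus_tag", "Name", "gene", "ID"):
            for name in feat.attributes.get(key, []):
                starts.setdefault(name, feat.start)
    return starts, genome_length
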