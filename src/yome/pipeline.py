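"""End-to-end orchestration: ingest -> categorize -> consensus -> analyses.

A single config (YAML file or dict) names every input — or a synthetic spec
to generate them — plus rule sets and thresholds. Outputs are written to a
directory: the final category TSV, a summary JSON, analysis TSVs and a log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import categorize, chromosome, coexpression, consensus, crosstab, expression, terms
from .kb_ingest import load_feature_store, save_store
from .synth import SyntheticSpec, generate_all
from .types import Category, FINAL_CATEGORIES

logger = logging.getLogger(__name__)


def round_half_up(value: float, digits: int = 1) -> float:
    """Decimal half-up rounding (3.35 -> 3.4 at one digit)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize(categories: pd.DataFrame, table: "consensus.FinalTable | None" = None) -> dict:
    """Counts and half-up one-decimal percentages by final category."""
    total = len(categories)
    counts = {c.value: int((categories["category"] == c.value).sum())
              for c in FINAL_CATEGORIES}
    percentages = {
        c: (round_half_up(100.0 * n / total) if total else 0.0)
        for c, n in counts.items()
    }
    summary = {
        "total": total,
        "counts": counts,
        "percentages": percentages,
        "basis_counts": dict(table.basis_counts) if table else {},
        "no_info_count": int(table.no_info_count) if table else int(
            categories.get("no_info", pd.Series(dtype=bool)).sum()
        ),
    }
    return summary


@dataclass
class PipelineConfig:
    """Run configuration; ``synthetic`` generates inputs when paths are absent."""

    outdir: Path
    kb_paths: dict[str, str] = field(default_factory=dict)
    overrides_path: str | None = None
    counts_path: str | None = None
    lengths_path: str | None = None
    samples_path: str | None = None
    positions_path: str | None = None
    modules_path: str | None = None
    gene_list_path: str | None = None
    rules_path: str | None = None
    word_sets_path: str | None = None
    synthetic: SyntheticSpec | None = None
    strict: bool = True
    r2_threshold: float = 0.9
    percentile: float = 20.0
    kappa: float = 50.0
    enrichment_window: float = float(np.pi / 4)
    genome_length: int = chromosome.DEFAULT_GENOME_LENGTH
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        synth_raw = raw.pop("synthetic", None)
        cfg = cls(outdir=Path(raw.pop("outdir", "yome_out")), **raw)
        if synth_raw is not None:
            cfg.synthetic = SyntheticSpec(**synth_raw)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; return the summary dict.

    Raises before any stage runs if a named input file is missing. In strict
    mode, unresolved genes without overrides abort the run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None and not config.kb_paths:
        spec = config.synthetic
        manifest = generate_all(spec, outdir / "synthetic_inputs")
        files = manifest["files"]
        config.kb_paths = {
            kb: files[f"kb_{kb}"] for kb in ("ecocyc", "ecogene", "uniprot", "regulondb")
        }
        config.overrides_path = files["overrides"]
        config.counts_path = files["counts"]
        config.lengths_path = files["gene_lengths"]
        config.samples_path = files["samples"]
        config.positions_path = files["positions"]
        config.modules_path = files["modules"]
        config.genome_length = spec.genome_length

    for name, path in {
        "kb": list(config.kb_paths.values()),
        "overrides": [config.overrides_path],
        "counts": [config.counts_path],
        "samples": [config.samples_path],
        "positions": [config.positions_path],
        "modules": [config.modules_path],
    }.items():
        for p in path:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")
    if not config.kb_paths:
        raise ValueError("no knowledge-base inputs configured")

    # Stage 1: ingest.
    store, row_errors = load_feature_store(config.kb_paths)
    save_store(store, outdir / "feature_store.sqlite")
    logger.info("ingested %d genes, %d features", len(store.genes), len(store.features))

    # Stage 2: per-KB categorization.
    rules = categorize.load_rules(config.rules_path)
    assignments = categorize.classify_store(store, rules)

    # Stage 3: consensus + overrides.
    overrides = (
        consensus.read_overrides(config.overrides_path)
        if config.overrides_path
        else {}
    )
    table = consensus.run_consensus(
        store, assignments, rules, overrides, strict=config.strict
    )
    cat_df = consensus.write_category_table(table, store, outdir / "categories.tsv")
    summary = summarize(cat_df, table)

    # Stage 4: analyses (each optional on its inputs).
    if config.counts_path:
        expr = expression.ExpressionSet.from_tsv(
            config.counts_path, config.lengths_path, config.samples_path
        ).compute()
        expr, qc = expression.replicate_qc(expr, config.r2_threshold)
        means = expression.mean_expression(expr)
        contrast = expression.compare_categories(means, cat_df)
        threshold, top_genes = expression.percentile_threshold(means, config.percentile)
        means.to_frame().to_csv(outdir / "mean_log_tpm.tsv", sep="\t")
        summary["expression"] = {
            "t_statistic": contrast.t_statistic,
            "p_value": contrast.p_value,
            "group_means": contrast.group_means,
            "qc_removed_conditions": qc.removed_conditions,
            "top_percentile_threshold": threshold,
            "top_percentile_n_genes": int(len(top_genes)),
        }

    if config.positions_path:
        pos = pd.read_csv(config.positions_path, sep="\t")
        cat_of = dict(zip(cat_df["gene_id"], cat_df["category"]))
        angles_by_cat: dict[str, np.ndarray] = {}
        for cat in sorted(set(cat_of.values())):
            starts = pos.loc[pos["gene_id"].map(cat_of) == cat, "start"].to_numpy()
            if len(starts):
                angles_by_cat[cat] = chromosome.to_angles(starts, config.genome_length)
        dens_rows = {}
        for cat, angles in angles_by_cat.items():
            dens = chromosome.vonmises_kde(angles, kappa=config.kappa)
            dens_rows[cat] = dens.density
            grid = dens.grid
        pd.DataFrame({"angle": grid, **dens_rows}).to_csv(
            outdir / "chromosome_density.tsv", sep="\t", index=False
        )
        enrich = chromosome.region_enrichment(
            angles_by_cat, window=config.enrichment_window
        )
        summary["chromosome"] = {
            "ter_ori_ratio": enrich.ratio,
            "ori_fraction": enrich.ori_fraction,
            "ter_fraction": enrich.ter_fraction,
        }

    if config.modules_path:
        modules = coexpression.read_modules(config.modules_path)
        mod_summary = coexpression.summarize_modules(modules, cat_df)
        ranked = coexpression.rank_candidate_genes(modules, cat_df)
        mod_summary.per_module.rename_axis("module_id").to_csv(
            outdir / "module_composition.tsv", sep="\t"
        )
        ranked.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)
        summary["modules"] = {
            "n_modules": mod_summary.n_modules,
            "totals": mod_summary.totals,
            "n_candidates": int(len(ranked)),
        }

    word_sets = terms.load_word_sets(config.word_sets_path)
    term_table = terms.count_word_sets(store, cat_df, word_sets)
    term_table.to_csv(outdir / "term_frequency.tsv", sep="\t")

    xtab = crosstab.yname_crosstab(cat_df)
    xtab.rename_axis("name_prefix").to_csv(outdir / "yname_crosstab.tsv", sep="\t")
    summary["yname_crosstab"] = {
        prefix: {c: int(xtab.loc[prefix, c]) for c in xtab.columns}
        for prefix in xtab.index
    }

    if config.gene_list_path:
        external = crosstab.read_gene_list(config.gene_list_path)
        comparison = crosstab.compare_gene_set(cat_df, external)
        summary["gene_set_comparison"] = {
            "counts": comparison.counts,
            "n_unmatched": len(comparison.unmatched),
        }

    if row_errors:
        summary["ingest_row_errors"] = {
            kb: len(errs) for kb, errs in row_errors.items()
        }

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
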