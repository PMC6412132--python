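"""Synthetic knowledge-base suites with planted ground truth.

Every pipeline input can be generated here with a known answer, so the
whole workflow is testable without downloading any knowledge base:

* four canonical feature tables whose planted features guarantee that the
  categorization and consensus rules recover each gene's true label —
  well-annotated genes receive experimental-evidence features (assay
  evidence, a high annotation score, a reaction equation or strong
  transcription-factor evidence), y-ome genes receive low-annotation
  keywords or low annotation scores, and excluded genes receive pseudogene /
  phantom flags or the apostrophe naming convention;
* optionally, *conflicting* genes carrying contradictory definite votes in
  different knowledge bases, paired with a generated manual-override entry
  carrying the true label;
* a counts matrix with replicate structure in which y-ome genes are
  systematically lower expressed by ``delta`` log2 units;
* circular gene start positions with the y-ome concentrated opposite the
  replication origin;
* co-expression module assignments mixing categories.

All generators are deterministic under a fixed seed (byte-identical files).
Planted category counts are exact at any n via largest-remainder
apportionment of the requested fractions.
"""

from __future__ import annotations

import functools
import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chromosome import DEFAULT_GENOME_LENGTH, DEFAULT_ORI_BP, TWO_PI
from .kb_ingest import FEATURE_TABLE_COLUMNS
from .types import Category

#: Fraction of y-ome genes given a 'y' primary name, and of well-annotated
#: genes given one, emulating the observed drift between naming convention
#: and annotation status.
YOME_Y_NAME_RATE = 0.71
WELL_Y_NAME_RATE = 0.06

_WELL_DESCRIPTIONS = [
    "ATP synthase membrane subunit",
    "DNA-binding transcriptional regulator of sugar metabolism",
    "periplasmic binding protein of an ABC transporter",
    "enzyme of aerobic phosphate metabolism",
    "outer membrane lipoprotein involved in stress resistance",
    "oxidoreductase acting in biofilm synthesis",
    "inner membrane transport protein",
    "translation initiation factor binding the ribosome",
]
_YOME_DESCRIPTIONS = [
    "predicted inner membrane transporter",
    "hypothetical protein",
    "possibly involved in stress response signal transduction",
    "predicted DNA-binding transcriptional regulator",
    "hypothetical periplasmic lipoprotein",
    "predicted oxidoreductase of sugar metabolism",
]
_NO_INFO_SUMMARY = (
    "No information about this protein was found by a literature search"
)
_NO_INFO_DESCRIPTION = "Putative uncharacterized protein"


@dataclass
class ExpressionSpec:
    n_conditions: int = 78
    replicates_per_condition: int = 2
    delta: float = 2.0  # y-ome expression deficit, log2 units
    sigma: float = 0.2  # replicate noise, log2 units (typical technical noise)
    base_mean: float = 7.0  # well-annotated mean log2 expression


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study; defaults mirror the observed E. coli
    category proportions (1600 y-ome / 2803 well-annotated / 220 excluded of
    4623 unique genes) and the observed no-information rate (111 of 1600)."""

    n_genes: int = 1000
    category_fractions: tuple[float, float, float] = (
        1600 / 4623, 2803 / 4623, 220 / 4623,
    )
    conflict_rate: float = 0.0
    no_info_rate: float = 111 / 1600
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    position_bias: float = 2.0  # von Mises concentration of y-ome toward ter
    genome_length: int = DEFAULT_GENOME_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.expression, (tuple, list)):
            self.expression = ExpressionSpec(*self.expression)
        elif isinstance(self.expression, dict):
            self.expression = ExpressionSpec(**self.expression)
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        fr = self.category_fractions
        if len(fr) != 3 or any(not 0 <= f <= 1 for f in fr):
            raise ValueError("category_fractions must be three values in [0,1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("category_fractions must sum to 1")
        for name in ("conflict_rate", "no_info_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")


def apportion(total: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment: integer counts summing to total."""
    raw = [total * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    shortfall = total - sum(counts)
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


@functools.lru_cache(maxsize=4)
def _name_combos(prefix_letters: str) -> tuple[str, ...]:
    letters = string.ascii_lowercase
    return tuple(
        f"{a}{b}{c}{d.upper()}"
        for a in prefix_letters
        for b in letters
        for c in letters
        for d in letters
        if not f"{a}{b}{c}".startswith("ins")
    )


def _name_pool(prefix_letters: str, rng: np.random.Generator):
    """Deterministic unique gene-name generator (shuffled by the run's rng)."""
    combos = _name_combos(prefix_letters)
    order = rng.permutation(len(combos))
    return (combos[i] for i in order)


@dataclass
class TruthTable:
    """Planted ground truth for one synthetic suite."""

    labels: pd.DataFrame  # gene_id, primary_name, category, no_info, conflict

    def category_of(self) -> dict[str, str]:
        return dict(zip(self.labels["gene_id"], self.labels["category"]))


def plant_labels(spec: SyntheticSpec) -> TruthTable:
    """Assign gene ids, names and true categories per the spec fractions."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    n_yome, n_well, n_excl = apportion(n, tuple(spec.category_fractions))
    categories = (
        [Category.YOME.value] * n_yome
        + [Category.WELL_ANNOTATED.value] * n_well
        + [Category.EXCLUDED.value] * n_excl
    )
    rng.shuffle(categories)

    y_names = _name_pool("y", rng)
    other_names = _name_pool("abcdefghjklmnopqrstuvwx", rng)
    rows = []
    for i, cat in enumerate(categories):
        gene_id = f"b{i + 1:04d}"
        y_rate = YOME_Y_NAME_RATE if cat == Category.YOME.value else WELL_Y_NAME_RATE
        name = next(y_names) if rng.random() < y_rate else next(other_names)
        rows.append({"gene_id": gene_id, "primary_name": name, "category": cat})
    labels = pd.DataFrame(rows)

    yome_idx = labels.index[labels["category"] == Category.YOME.value].to_numpy()
    n_no_info = int(round(spec.no_info_rate * len(yome_idx)))
    no_info_idx = rng.choice(yome_idx, size=n_no_info, replace=False)
    labels["no_info"] = False
    labels.loc[no_info_idx, "no_info"] = True

    definite_idx = labels.index[
        (labels["category"] != Category.EXCLUDED.value) & ~labels["no_info"]
    ].to_numpy()
    n_conflict = int(round(spec.conflict_rate * n))
    if n_conflict > len(definite_idx):
        raise ValueError("conflict_rate too high for the available genes")
    conflict_idx = rng.choice(definite_idx, size=n_conflict, replace=False)
    labels["conflict"] = False
    labels.loc[conflict_idx, "conflict"] = True

    # Apostrophe-convention pseudogene names for half the excluded genes.
    excl_idx = labels.index[labels["category"] == Category.EXCLUDED.value].to_numpy()
    labels["apostrophe"] = False
    labels.loc[excl_idx[: len(excl_idx) // 2], "apostrophe"] = True
    labels.loc[labels["apostrophe"], "primary_name"] += "'"
    return TruthTable(labels=labels)


def generate_kb_suite(
    spec: SyntheticSpec, outdir: str | Path
) -> tuple[dict[str, Path], Path, Path]:
    """Write four feature tables, the truth labels and the override table.

    Returns (kb paths by name, labels path, overrides path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = plant_labels(spec)
    rng = np.random.default_rng(spec.seed + 1)

    tables: dict[str, list[tuple[str, ...]]] = {
        kb: [] for kb in ("ecocyc", "ecogene", "uniprot", "regulondb")
    }
    overrides: list[dict[str, str]] = []

    def row(kb: str, gene_id: str, name: str, ftype: str, value: str) -> None:
        tables[kb].append((kb, gene_id, name, "", ftype, value))

    for rec in truth.labels.itertuples(index=False):
        gid, name, cat = rec.gene_id, rec.primary_name, rec.category
        if cat == Category.EXCLUDED.value:
            if rec.apostrophe:
                row("ecogene", gid, name, "description", "interrupted coding sequence")
                row("ecocyc", gid, name, "description", "")
            else:
                flag = "pseudogene_flag" if rng.random() < 0.5 else "phantom_flag"
                row("ecocyc", gid, name, flag, "true")
                row("ecogene", gid, name, "description", "")
            continue
        if rec.conflict:
            if cat == Category.WELL_ANNOTATED.value:
                # EcoCyc says y-ome, UniProt says well-annotated.
                row("ecocyc", gid, name, "description",
                    str(rng.choice(_YOME_DESCRIPTIONS)))
                row("uniprot", gid, name, "annotation_score", "5")
            else:
                # EcoCyc says well-annotated, UniProt says y-ome.
                row("ecocyc", gid, name, "reaction_equation", "A + B -> C + D")
                row("uniprot", gid, name, "annotation_score",
                    str(rng.integers(1, 3)))
            overrides.append(
                {
                    "gene_id": gid,
                    "category": cat,
                    "justification": "conflicting knowledge-base evidence reviewed",
                    "curator": "synth",
                    "date": "2019-01-01",
                }
            )
            continue
        if cat == Category.YOME.value:
            if rec.no_info:
                row("ecocyc", gid, name, "summary", _NO_INFO_SUMMARY)
                row("uniprot", gid, name, "description", _NO_INFO_DESCRIPTION)
                if rng.random() < 0.5:
                    row("uniprot", gid, name, "domain_only",
                        f"DUF{rng.integers(1000, 5000)}")
            else:
                row("ecocyc", gid, name, "description",
                    str(rng.choice(_YOME_DESCRIPTIONS)))
                if rng.random() < 0.5:
                    row("uniprot", gid, name, "annotation_score",
                        str(rng.integers(1, 3)))
            continue
        # Well-annotated: plant one of several evidence mechanisms.
        mechanism = rng.choice(["evidence", "score", "reaction", "regulondb", "combo"])
        desc = str(rng.choice(_WELL_DESCRIPTIONS))
        if mechanism == "evidence":
            row("ecocyc", gid, name, "description", desc)
            row("ecocyc", gid, name, "evidence", "Assay of purified protein")
        elif mechanism == "score":
            row("ecocyc", gid, name, "description", desc)
            row("uniprot", gid, name, "annotation_score", str(rng.integers(4, 6)))
        elif mechanism == "reaction":
            row("ecocyc", gid, name, "description", desc)
            row("ecocyc", gid, name, "reaction_equation", "substrate -> product")
        elif mechanism == "regulondb":
            row("ecocyc", gid, name, "description", desc)
            row("regulondb", gid, name, "tf_evidence", "Strong")
        else:  # combo: EcoCyc and UniProt both well-annotated
            row("ecocyc", gid, name, "reaction_equation", "substrate -> product")
            row("ecocyc", gid, name, "description", desc)
            row("uniprot", gid, name, "annotation_score", "5")
        row("ecogene", gid, name, "description", desc)

    paths: dict[str, Path] = {}
    for kb, rows in tables.items():
        path = outdir / f"{kb}_features.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(FEATURE_TABLE_COLUMNS) + "\n")
            for r in rows:
                fh.write("\t".join(r) + "\n")
        paths[kb] = path

    labels_path = outdir / "truth_labels.tsv"
    truth.labels.to_csv(labels_path, sep="\t", index=False)
    overrides_path = outdir / "overrides.tsv"
    pd.DataFrame(
        overrides, columns=["gene_id", "category", "justification", "curator", "date"]
    ).to_csv(overrides_path, sep="\t", index=False)
    return paths, labels_path, overrides_path


def generate_expression(
    spec: SyntheticSpec, labels: pd.DataFrame, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Write counts, gene-length and sample-metadata TSVs.

    Per-gene expected log2 expression is Normal(mu_cat, 1) with the y-ome
    mean delta units below the well-annotated mean (excluded genes share the
    y-ome mean); each replicate draws log2 noise sigma around the gene's
    condition mean, and counts are rounded length-scaled powers of two.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ex = spec.expression
    rng = np.random.default_rng(spec.seed + 2)
    gene_ids = labels["gene_id"].to_numpy()
    cats = labels["category"].to_numpy()
    mu = np.where(
        cats == Category.WELL_ANNOTATED.value,
        ex.base_mean,
        ex.base_mean - ex.delta,
    )
    gene_means = rng.normal(mu, 1.0)
    lengths = rng.integers(300, 3001, size=len(gene_ids))

    sample_rows = []
    data = {}
    for c in range(ex.n_conditions):
        cond = f"cond{c + 1:03d}"
        for r in range(ex.replicates_per_condition):
            sid = f"{cond}_r{r + 1}"
            sample_rows.append(
                {"sample_id": sid, "condition_id": cond, "replicate_id": f"r{r + 1}"}
            )
            log_expr = gene_means + (
                rng.normal(0.0, ex.sigma, size=len(gene_ids)) if ex.sigma > 0 else 0.0
            )
            counts = np.rint(np.power(2.0, log_expr) * lengths / 1000.0)
            data[sid] = np.maximum(counts, 0).astype(np.int64)

    counts_df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    counts_path = outdir / "counts.tsv"
    counts_df.to_csv(counts_path, sep="\t")
    lengths_path = outdir / "gene_lengths.tsv"
    pd.DataFrame(
        {"gene_id": gene_ids, "length": lengths}
    ).to_csv(lengths_path, sep="\t", index=False)
    samples_path = outdir / "samples.tsv"
    pd.DataFrame(sample_rows).to_csv(samples_path, sep="\t", index=False)
    return counts_path, lengths_path, samples_path


def generate_positions(
    spec: SyntheticSpec, labels: pd.DataFrame, outdir: str | Path
) -> Path:
    """Write the positions TSV: y-ome starts von Mises-concentrated at the
    terminus, all other categories uniform; starts are distinct integers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    L = spec.genome_length
    if L <= spec.n_genes:
        raise ValueError("genome_length must exceed n_genes")
    rng = np.random.default_rng(spec.seed + 3)
    ori_angle = TWO_PI * (DEFAULT_ORI_BP - 1) / DEFAULT_GENOME_LENGTH
    ter_angle = (ori_angle + np.pi) % TWO_PI

    cats = labels["category"].to_numpy()
    n = len(cats)
    angles = rng.uniform(0.0, TWO_PI, size=n)
    yome_mask = cats == Category.YOME.value
    if spec.position_bias > 0:
        angles[yome_mask] = (
            ter_angle + rng.vonmises(0.0, spec.position_bias, size=yome_mask.sum())
        ) % TWO_PI
    starts = (np.floor(angles / TWO_PI * L).astype(np.int64) + 1).clip(1, L)
    # Resolve duplicate coordinates deterministically.
    seen: set[int] = set()
    for i in range(n):
        s = int(starts[i])
        while s in seen:
            s = s % L + 1
        seen.add(s)
        starts[i] = s
    path = Path(outdir) / "positions.tsv"
    pd.DataFrame({"gene_id": labels["gene_id"], "start": starts}).to_csv(
        path, sep="\t", index=False
    )
    return path


def generate_modules(
    labels: pd.DataFrame,
    outdir: str | Path,
    n_modules: int = 12,
    mixing: float = 0.3,
    min_size: int = 10,
    max_size: int = 30,
    seed: int = 0,
) -> Path:
    """Write the module-assignment TSV (gene_id, module_id).

    Each module has at least ``min_size`` members and each gene joins at
    most one module. ``mixing`` is the y-ome fraction per module; 0 yields
    single-category modules.
    """
    rng = np.random.default_rng(seed + 4)
    well_pool = list(
        labels.loc[labels["category"] == Category.WELL_ANNOTATED.value, "gene_id"]
    )
    yome_pool = list(labels.loc[labels["category"] == Category.YOME.value, "gene_id"])
    rng.shuffle(well_pool)
    rng.shuffle(yome_pool)
    rows = []
    for m in range(n_modules):
        size = int(rng.integers(min_size, max_size + 1))
        module_id = f"M{m + 1:02d}"
        if mixing == 0:
            pool = well_pool if m % 2 == 0 else yome_pool
            if len(pool) < size:
                break
            members = [pool.pop() for _ in range(size)]
        else:
            n_yome = max(0, min(int(round(mixing * size)), size))
            n_well = size - n_yome
            if len(yome_pool) < n_yome or len(well_pool) < n_well:
                break
            members = [yome_pool.pop() for _ in range(n_yome)] + [
                well_pool.pop() for _ in range(n_well)
            ]
        rows.extend({"gene_id": g, "module_id": module_id} for g in members)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "modules.tsv"
    pd.DataFrame(rows, columns=["gene_id", "module_id"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def generate_all(spec: SyntheticSpec, outdir: str | Path) -> dict[str, object]:
    """Generate the complete input suite plus a manifest JSON."""
    outdir = Path(outdir)
    kb_paths, labels_path, overrides_path = generate_kb_suite(spec, outdir)
    labels = pd.read_csv(labels_path, sep="\t")
    counts, lengths, samples = generate_expression(spec, labels, outdir)
    positions = generate_positions(spec, labels, outdir)
    modules = generate_modules(labels, outdir, seed=spec.seed)
    manifest = {
        "spec": {
            **{k: v for k, v in asdict(spec).items() if k != "expression"},
            "expression": asdict(spec.expression),
        },
        "files": {
            **{f"kb_{k}": str(p) for k, p in kb_paths.items()},
            "labels": str(labels_path),
            "overrides": str(overrides_path),
            "counts": str(counts),
            "gene_lengths": str(lengths),
            "samples": str(samples),
            "positions": str(positions),
            "modules": str(modules),
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
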