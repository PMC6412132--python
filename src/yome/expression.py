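"""Expression compendium handling: TPM, replicate QC, category contrasts.

Counts are normalized to transcripts per million (TPM): per-gene count rates
``count/length`` are scaled so that each sample sums to 1e6, then
log-transformed as ``log2(TPM + 1)``. Biological replicates whose pairwise
squared Pearson correlation (R²) of log-TPM falls below a threshold (default
0.9) are removed as a group to reduce technical noise. Mean expression per
gene averages replicates within each condition first, then across
conditions. The y-ome vs well-annotated contrast is a Welch (unequal
variance) two-sample t-test on these per-gene means, visualized as empirical
cumulative distributions per category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .types import Category


@dataclass
class ExpressionSet:
    """Counts plus derived TPM / log-TPM matrices and sample metadata.

    ``counts`` is genes x samples; ``samples`` carries columns sample_id,
    condition_id, replicate_id indexed like the count columns.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame
    tpm: pd.DataFrame | None = None
    log_tpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_lengths.index):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if self.gene_lengths.isna().any():
                raise ValueError("gene_lengths missing for some count rows")
        meta_ids = list(self.samples["sample_id"])
        if sorted(meta_ids) != sorted(self.counts.columns):
            raise ValueError("sample metadata does not match count columns")

    def compute(self) -> "ExpressionSet":
        self.tpm = tpm_from_counts(self.counts, self.gene_lengths)
        self.log_tpm = np.log2(self.tpm + 1.0)
        return self

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, lengths_path: str | Path, samples_path: str | Path
    ) -> "ExpressionSet":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        samples = pd.read_csv(samples_path, sep="\t", dtype=str)
        return cls(counts=counts, gene_lengths=lengths, samples=samples)


def tpm_from_counts(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from a raw counts matrix.

    rate_i = count_i / length_i; TPM_i = 1e6 * rate_i / sum_j rate_j,
    per sample. Every column of the result sums to 1e6.
    """
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene lengths: {bad[:5]}")
    zero = counts.columns[(counts.sum(axis=0) == 0)]
    if len(zero):
        raise ValueError(f"all-zero count column(s): {list(zero)}")
    rates = counts.div(lengths, axis=0)
    return rates.div(rates.sum(axis=0), axis=1) * 1e6


@dataclass
class QCReport:
    removed_samples: list[str] = field(default_factory=list)
    removed_conditions: list[str] = field(default_factory=list)
    group_r2: dict[str, float] = field(default_factory=dict)
    not_applicable: list[str] = field(default_factory=list)


def replicate_qc(
    expr: ExpressionSet, r2_threshold: float = 0.9
) -> tuple[ExpressionSet, QCReport]:
    """Drop replicate groups with poor within-condition agreement.

    For each condition with >= 2 replicates, the minimum pairwise R²
    (squared Pearson correlation of log-TPM across genes) is computed; if it
    falls below the threshold the whole replicate group is removed.
    Single-replicate conditions are retained and flagged as not applicable.
    """
    if expr.log_tpm is None:
        expr.compute()
    report = QCReport()
    keep: list[str] = []
    for condition, group in expr.samples.groupby("condition_id", sort=True):
        sample_ids = list(group["sample_id"])
        if len(sample_ids) < 2:
            report.not_applicable.append(str(condition))
            keep.extend(sample_ids)
            continue
        r2s = [
            np.corrcoef(expr.log_tpm[a], expr.log_tpm[b])[0, 1] ** 2
            for a, b in combinations(sample_ids, 2)
        ]
        worst = float(min(r2s))
        report.group_r2[str(condition)] = worst
        if worst < r2_threshold:
            report.removed_samples.extend(sample_ids)
            report.removed_conditions.append(str(condition))
        else:
            keep.extend(sample_ids)
    if not keep:
        raise ValueError("replicate QC removed every sample")
    filtered = ExpressionSet(
        counts=expr.counts[keep],
        gene_lengths=expr.gene_lengths,
        samples=expr.samples[expr.samples["sample_id"].isin(keep)].reset_index(drop=True),
    ).compute()
    return filtered, report


def mean_expression(expr: ExpressionSet) -> pd.Series:
    """Per-gene mean log-TPM: replicates averaged within condition first,
    then the mean taken across conditions."""
    if expr.log_tpm is None:
        expr.compute()
    cond_of = dict(zip(expr.samples["sample_id"], expr.samples["condition_id"]))
    cond_means = expr.log_tpm.T.groupby(
        expr.log_tpm.columns.map(cond_of)
    ).mean()  # conditions x genes
    return cond_means.mean(axis=0).rename("mean_log_tpm")


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and cumulative probabilities in (0, 1]."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, len(x) + 1) / len(x)
    return x, y


@dataclass
class CategoryExpressionSummary:
    t_statistic: float
    p_value: float
    ecdfs: dict[str, tuple[np.ndarray, np.ndarray]]
    group_means: dict[str, float]
    missing_genes: list[str] = field(default_factory=list)


def compare_categories(
    means: pd.Series,
    categories: pd.DataFrame,
    group_a: Category = Category.YOME,
    group_b: Category = Category.WELL_ANNOTATED,
) -> CategoryExpressionSummary:
    """Welch t-test of mean log-TPM between two gene categories.

    ``categories`` is the final category table (columns gene_id, category).
    ECDFs are returned for every category present, including excluded. Genes
    in the category table but absent from the expression matrix are reported
    separately, not treated as zeros.
    """
    cat_map = dict(zip(categories["gene_id"], categories["category"]))
    missing = [g for g in cat_map if g not in means.index]
    groups: dict[str, np.ndarray] = {}
    for cat in sorted(set(cat_map.values())):
        members = [g for g, c in cat_map.items() if c == cat and g in means.index]
        groups[cat] = means.loc[members].to_numpy()
    a = groups.get(group_a.value, np.array([]))
    b = groups.get(group_b.value, np.array([]))
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"compare_categories needs >=2 genes per group "
            f"({group_a.value}: {len(a)}, {group_b.value}: {len(b)})"
        )
    if np.array_equal(np.sort(a), np.sort(b)) and np.ptp(a) == 0 and np.ptp(b) == 0:
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=False)
    return CategoryExpressionSummary(
        t_statistic=float(t_stat),
        p_value=float(p_val),
        ecdfs={cat: ecdf(vals) for cat, vals in groups.items() if len(vals)},
        group_means={cat: float(np.mean(v)) for cat, v in groups.items() if len(v)},
        missing_genes=missing,
    )


def percentile_threshold(
    means: pd.Series, q: float = 20.0
) -> tuple[float, pd.Index]:
    """Threshold for the top q% of expression and the genes strictly above it.

    The threshold is the (100-q)-th percentile under numpy's linear
    interpolation convention.
    """
    if not 0 < q < 100:
        raise ValueError(f"percentile q must be in (0, 100), got {q}")
    threshold = float(np.percentile(means.to_numpy(dtype=float), 100 - q))
    return threshold, means.index[means > threshold]
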