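"""TPM normalization, replicate QC, mean expression and category contrast."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from yome.expression import (
    ExpressionSet,
    compare_categories,
    mean_expression,
    percentile_threshold,
    replicate_qc,
    tpm_from_counts,
)


def make_expr(counts: dict, lengths: dict, samples: list[tuple[str, str, str]]):
    counts_df = pd.DataFrame(counts)
    counts_df.index = list(lengths)
    return ExpressionSet(
        counts=counts_df,
        gene_lengths=pd.Series(lengths),
        samples=pd.DataFrame(samples, columns=["sample_id", "condition_id", "replicate_id"]),
    )


class TestTpm:
    def test_equal_lengths_split_by_counts(self):
        counts = pd.DataFrame({"s1": [10, 90]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 1000})
        tpm = tpm_from_counts(counts, lengths)
        assert np.allclose(tpm["s1"], [1e5, 9e5])

    def test_length_normalization(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 2000})
        tpm = tpm_from_counts(counts, lengths)
        assert np.allclose(tpm["s1"], [2e6 / 3, 1e6 / 3])

    def test_single_gene_gets_everything(self):
        counts = pd.DataFrame({"s1": [7]}, index=["g1"])
        tpm = tpm_from_counts(counts, pd.Series({"g1": 123}))
        assert tpm["s1"].iloc[0] == pytest.approx(1e6)

    def test_all_zero_sample_is_an_error_naming_it(self):
        counts = pd.DataFrame({"bad": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="bad"):
            tpm_from_counts(counts, pd.Series({"g1": 100, "g2": 100}))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=2, max_size=30),
        st.integers(min_value=0, max_value=2**31),
    )
    def test_columns_always_sum_to_one_million(self, raw_counts, seed):
        if sum(raw_counts) == 0:
            raw_counts[0] = 1
        rng = np.random.default_rng(seed)
        lengths = rng.integers(100, 5000, size=len(raw_counts))
        counts = pd.DataFrame({"s": raw_counts})
        counts.index = [f"g{i}" for i in range(len(raw_counts))]
        tpm = tpm_from_counts(counts, pd.Series(lengths, index=counts.index))
        assert tpm["s"].sum() == pytest.approx(1e6, rel=1e-6)
        # log2(TPM+1) preserves the within-sample ordering.
        log_tpm = np.log2(tpm["s"] + 1)
        assert (tpm["s"].rank(method="average") == log_tpm.rank(method="average")).all()


class TestReplicateQC:
    def test_identical_replicates_retained(self):
        profile = list(np.arange(1, 21) * 10)
        expr = make_expr(
            {"a_r1": profile, "a_r2": profile},
            {f"g{i}": 1000 for i in range(20)},
            [("a_r1", "A", "r1"), ("a_r2", "A", "r2")],
        )
        filtered, report = replicate_qc(expr)
        assert report.group_r2["A"] == pytest.approx(1.0)
        assert not report.removed_samples

    def test_independent_noise_profiles_removed_as_group(self):
        rng = np.random.default_rng(42)
        genes = {f"g{i}": 1000 for i in range(200)}
        noisy1 = rng.integers(1, 2000, size=200)
        noisy2 = rng.integers(1, 2000, size=200)
        clean = np.arange(1, 201) * 7
        expr = make_expr(
            {
                "bad_r1": noisy1, "bad_r2": noisy2,
                "ok_r1": clean, "ok_r2": clean,
            },
            genes,
            [("bad_r1", "BAD", "r1"), ("bad_r2", "BAD", "r2"),
             ("ok_r1", "OK", "r1"), ("ok_r2", "OK", "r2")],
        )
        filtered, report = replicate_qc(expr, r2_threshold=0.9)
        assert report.group_r2["BAD"] < 0.9
        assert set(report.removed_samples) == {"bad_r1", "bad_r2"}
        assert report.removed_conditions == ["BAD"]
        assert list(filtered.counts.columns) == ["ok_r1", "ok_r2"]

    def test_single_replicate_condition_flagged_not_removed(self):
        expr = make_expr(
            {"only": [1, 2, 3]},
            {"g0": 100, "g1": 100, "g2": 100},
            [("only", "A", "r1")],
        )
        filtered, report = replicate_qc(expr)
        assert report.not_applicable == ["A"]
        assert list(filtered.counts.columns) == ["only"]


class TestMeanExpression:
    def test_replicates_average_within_condition_first(self):
        # log-TPM 2 and 4 in two replicates of A, 6 in B -> ((2+4)/2 + 6)/2.
        expr = make_expr(
            {"a1": [1], "a2": [1], "b1": [1]},
            {"g": 1000},
            [("a1", "A", "r1"), ("a2", "A", "r2"), ("b1", "B", "r1")],
        )
        expr.compute()
        expr.log_tpm = pd.DataFrame(
            {"a1": [2.0], "a2": [4.0], "b1": [6.0]}, index=["g"]
        )
        assert mean_expression(expr)["g"] == pytest.approx(4.5)

    def test_constant_gene_mean_is_the_constant(self):
        expr = make_expr(
            {"a1": [5, 1], "b1": [5, 2]},
            {"g0": 1000, "g1": 1000},
            [("a1", "A", "r1"), ("b1", "B", "r1")],
        )
        expr.compute()
        expr.log_tpm = pd.DataFrame(
            {"a1": [3.0, 1.0], "b1": [3.0, 9.0]}, index=["g0", "g1"]
        )
        means = mean_expression(expr)
        assert means["g0"] == pytest.approx(3.0)

    def test_planted_condition_means_recovered(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(10)]
        planted = rng.normal(5, 2, size=(10, 3))  # genes x conditions
        cols, samples = {}, []
        for c in range(3):
            for r in range(2):
                sid = f"c{c}_r{r}"
                cols[sid] = planted[:, c]
                samples.append((sid, f"c{c}", f"r{r}"))
        expr = make_expr(
            {k: [1] * 10 for k in cols}, {g: 1000 for g in genes}, samples
        )
        expr.compute()
        expr.log_tpm = pd.DataFrame(cols, index=genes)
        expected = planted.mean(axis=1)
        assert np.allclose(mean_expression(expr).loc[genes], expected, atol=1e-12)


class TestCompareCategories:
    def cat_table(self, mapping):
        return pd.DataFrame(
            [{"gene_id": g, "primary_name": g, "category": c} for g, c in mapping.items()]
        )

    def test_identical_groups_give_t0_p1(self):
        means = pd.Series({"a1": 1.0, "a2": 2.0, "b1": 1.0, "b2": 2.0})
        cats = self.cat_table(
            {"a1": "yome", "a2": "yome", "b1": "well_annotated", "b2": "well_annotated"}
        )
        res = compare_categories(means, cats)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(123)
        n = 300
        means = pd.Series(
            {f"y{i}": v for i, v in enumerate(rng.normal(4, 1, n))}
            | {f"w{i}": v for i, v in enumerate(rng.normal(6, 1, n))}
        )
        cats = self.cat_table(
            {f"y{i}": "yome" for i in range(n)}
            | {f"w{i}": "well_annotated" for i in range(n)}
        )
        res = compare_categories(means, cats)
        assert res.p_value < 1e-6
        assert res.t_statistic < 0  # y-ome lower

    def test_label_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(5)
        means = pd.Series(
            {f"g{i}": v for i, v in enumerate(rng.normal(0, 1, 40))}
        )
        mapping = {
            f"g{i}": ("yome" if i % 2 else "well_annotated") for i in range(40)
        }
        res = compare_categories(means, self.cat_table(mapping))
        swapped = {
            g: ("well_annotated" if c == "yome" else "yome") for g, c in mapping.items()
        }
        res2 = compare_categories(means, self.cat_table(swapped))
        assert res2.t_statistic == pytest.approx(-res.t_statistic)
        assert res2.p_value == pytest.approx(res.p_value)

    def test_ecdfs_are_nondecreasing_and_reach_one(self):
        rng = np.random.default_rng(9)
        means = pd.Series({f"g{i}": v for i, v in enumerate(rng.normal(0, 1, 30))})
        mapping = {f"g{i}": ("yome" if i < 15 else "well_annotated") for i in range(30)}
        res = compare_categories(means, self.cat_table(mapping))
        for x, y in res.ecdfs.values():
            assert (np.diff(x) >= 0).all()
            assert (np.diff(y) > 0).all() and y[-1] == pytest.approx(1.0)

    def test_tiny_group_rejected(self):
        means = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        cats = self.cat_table({"a": "yome", "b": "well_annotated", "c": "well_annotated"})
        with pytest.raises(ValueError):
            compare_categories(means, cats)


class TestPercentileThreshold:
    def brute_force(self, values, q):
        threshold = float(np.percentile(np.asarray(values, float), 100 - q))
        subset = sorted(v for v in values if v > threshold)
        return threshold, subset

    def test_top_twenty_percent_of_one_to_ten(self):
        means = pd.Series({f"g{v}": float(v) for v in range(1, 11)})
        threshold, genes = percentile_threshold(means, 20)
        want_threshold, want_subset = self.brute_force(list(range(1, 11)), 20)
        assert threshold == pytest.approx(want_threshold)
        assert sorted(means[genes]) == want_subset
        assert set(genes) == {"g9", "g10"}

    def test_all_equal_gives_empty_strictly_above(self):
        means = pd.Series({f"g{i}": 5.0 for i in range(10)})
        _, genes = percentile_threshold(means, 20)
        assert len(genes) == 0

    def test_q50_is_the_median(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        means = pd.Series({f"g{i}": v for i, v in enumerate(values)})
        threshold, _ = percentile_threshold(means, 50)
        assert threshold == pytest.approx(np.median(values))

    @pytest.mark.parametrize("q", [0, 100, -5])
    def test_invalid_percentile_rejected(self, q):
        with pytest.raises(ValueError):
            percentile_threshold(pd.Series([1.0, 2.0]), q)


def test_planted_effect_sign_recovered_across_seeds(tmp_path):
    """With a planted y-ome deficit of 1 log2 unit (300 genes/group), the
    t statistic of the generated compendium has the planted sign in >=99%
    of 100 seeded replications."""
    from yome.synth import ExpressionSpec, SyntheticSpec, generate_expression, plant_labels

    hits = 0
    n_rep = 100
    for seed in range(n_rep):
        spec = SyntheticSpec(
            n_genes=600,
            category_fractions=(0.5, 0.5, 0.0),
            expression=ExpressionSpec(n_conditions=8, delta=1.0, sigma=0.2),
            seed=seed,
        )
        labels = plant_labels(spec).labels
        counts_p, lengths_p, samples_p = generate_expression(spec, labels, tmp_path / str(seed))
        expr = ExpressionSet.from_tsv(counts_p, lengths_p, samples_p).compute()
        means = mean_expression(expr)
        cats = labels.rename(columns={})[["gene_id", "primary_name", "category"]]
        res = compare_categories(means, cats)
        hits += res.t_statistic < 0
    assert hits >= 99
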