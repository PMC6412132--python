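from __future__ import annotations

import pandas as pd
import pytest

from yome.categorize import classify_store, load_rules
from yome.consensus import read_overrides, run_consensus
from yome.kb_ingest import load_feature_store
from yome.synth import SyntheticSpec, generate_kb_suite


@pytest.fixture(scope="session")
def default_rules():
    return load_rules()


def run_suite(spec: SyntheticSpec, outdir):
    """Generate a KB suite and run it through ingest -> categorize -> consensus."""
    paths, labels_path, overrides_path = generate_kb_suite(spec, outdir)
    store, _ = load_feature_store(paths)
    rules = load_rules()
    assignments = classify_store(store, rules)
    overrides = read_overrides(overrides_path)
    table = run_consensus(store, assignments, rules, overrides, strict=True)
    labels = pd.read_csv(labels_path, sep="\t")
    return labels, table, store


@pytest.fixture(scope="session")
def small_suite(tmp_path_factory):
    """A 120-gene suite with conflicts, shared by read-only tests."""
    spec = SyntheticSpec(n_genes=120, conflict_rate=0.05, no_info_rate=0.1, seed=11)
    outdir = tmp_path_factory.mktemp("suite")
    labels, table, store = run_suite(spec, outdir)
    return spec, labels, table, store


def category_frame(table, store) -> pd.DataFrame:
    rows = [
        {
            "gene_id": g,
            "primary_name": store.genes[g].primary_name,
            "category": rec.category.value,
            "no_info": rec.no_info,
        }
        for g, rec in table.records.items()
    ]
    return pd.DataFrame(rows)
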