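"""Term-frequency table: unique genes per category matching each word set.

Knowledge-base free text for each gene is scanned for configurable *word
sets* (similar words grouped, e.g. transport/transporter/export/import).
Counting is by unique gene: a gene contributes at most one count per word
set and category regardless of how many member words or features match.
Matching is case-insensitive on whole words after tokenization on
non-alphanumeric characters — substring matching would conflate e.g.
"transport" and "transporter", which are distinct set members.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .kb_ingest import FeatureStore
from .types import FeatureType

#: Feature types scanned for words by default.
DEFAULT_SCAN_TYPES = (FeatureType.DESCRIPTION, FeatureType.SUMMARY)

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


@dataclass(frozen=True)
class WordSet:
    label: str
    words: frozenset[str]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError(f"word set {self.label!r} is empty")
        object.__setattr__(self, "words", frozenset(w.lower() for w in self.words))


def load_word_sets(path: str | Path | None = None) -> list[WordSet]:
    if path is None:
        text = (
            importlib.resources.files("yome.data")
            .joinpath("default_word_sets.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    return [
        WordSet(label=ws["label"], words=frozenset(ws["words"]))
        for ws in raw["word_sets"]
    ]


def tokenize(text: str) -> set[str]:
    return {tok for tok in _TOKEN_RE.split(text.lower()) if tok}


def count_word_sets(
    store: FeatureStore,
    categories: pd.DataFrame,
    word_sets: list[WordSet],
    scan_types: tuple[FeatureType, ...] = DEFAULT_SCAN_TYPES,
) -> pd.DataFrame:
    """Word set x category table of unique-gene counts.

    Rows are word-set labels, columns the final categories; each cell is the
    number of unique genes of that category with at least one scanned
    feature containing at least one member word.
    """
    cat_map = dict(zip(categories["gene_id"], categories["category"]))
    tokens_by_gene: dict[str, set[str]] = {}
    for feat in store.features:
        if feat.feature_type in scan_types and feat.gene_ref in cat_map:
            tokens_by_gene.setdefault(feat.gene_ref, set()).update(tokenize(feat.value))
    cat_values = sorted(set(cat_map.values()))
    counts = {ws.label: {c: 0 for c in cat_values} for ws in word_sets}
    for gene_id, tokens in tokens_by_gene.items():
        cat = cat_map[gene_id]
        for ws in word_sets:
            if tokens & ws.words:
                counts[ws.label][cat] += 1
    df = pd.DataFrame.from_dict(counts, orient="index")[cat_values]
    df.index.name = "word_set"
    return df
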