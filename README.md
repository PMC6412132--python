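# yome

Determine the **y-ome** — the set of genes in a genome that lack
experimental evidence of function with a mechanistic link to phenotype — by
integrating annotations across knowledge bases, and characterize it with
expression, chromosome-location and co-expression analyses.

The package is aimed at microbial genome curators and systems biologists
working with *Escherichia coli* K-12 MG1655 (or any organism with several
partially overlapping annotation resources). Knowledge bases such as
EcoCyc, EcoGene, UniProt and RegulonDB frequently disagree about how well a
gene is annotated, and the historical 'y'-name convention for
uncharacterized open reading frames no longer tracks annotation status.
This package makes the categorization reproducible.

## The workflow

1. **Ingest.** Each knowledge base is normalized to a canonical TSV feature
   table (`kb, locus_tag, primary_name, synonyms, feature_type,
   feature_value`). A unique-gene registry is resolved across sources
   (locus tag > exact primary-name match > synonym match) and everything is
   stored in a single-file SQLite database. Gene start positions come from
   a GenBank or GFF3 genome annotation.
2. **Per-KB categorization.** A data-driven rule engine assigns each gene a
   category per knowledge base: *y-ome*, *well-annotated*, *excluded*
   (pseudogenes and phantom genes), or *not enough information*. Rules are
   case-insensitive keyword matches (e.g. `predicted`, `hypothetical` ⇒
   y-ome; curated evidence terms like `assay` ⇒ well-annotated) plus
   structured rules: UniProt annotation score ≤ 2 ⇒ y-ome, ≥ 4 ⇒
   well-annotated; reaction equations, complex membership and insertion
   elements ⇒ well-annotated; pseudogene/phantom flags and EcoGene's
   apostrophe names ⇒ excluded. Within one KB, conflicts resolve by the
   precedence excluded > well-annotated > y-ome.
3. **Consensus.** Per-KB votes combine in a fixed order: exclusion first;
   then four high-trust exceptions that force *well-annotated* (EcoCyc
   evidence-ontology keywords; RegulonDB `Strong` transcription-factor
   evidence; EcoCyc and UniProt agreeing on well-annotated; insertion
   elements); then agreement among definite votes; remaining disagreements
   are decided by a manual-override table or flagged unresolved. Genes with
   no information anywhere (stock phrases like "No information about
   this…", "Putative uncharacterized…", or domain-only annotations) are
   flagged `no_info` inside the y-ome.
4. **Analyses.** Counts → TPM (`TPM_i = 10^6 (c_i/l_i) / Σ_j (c_j/l_j)`) →
   `log2(TPM+1)`; replicate groups with pairwise R² < 0.9 are dropped; the
   y-ome vs well-annotated contrast is a Welch t-test on per-gene mean
   log-TPM. Gene-start density on the circular chromosome uses a von Mises
   kernel density estimate `f(θ) = (1/n) Σ_i e^{κ cos(θ−θ_i)} / (2π I_0(κ))`
   with ORI/terminus window enrichment ratios. Externally detected
   co-expression modules are summarized by category and y-ome members are
   ranked by the well-annotated fraction of their module. Term-frequency
   tables and a 'y'-name × category crosstab round out the reporting.

A synthetic-data generator (`yome.synth`) emits every input format with
planted ground truth, so the entire workflow is testable offline.

## Worked example

```bash
yome run-all --out readme_demo --n-genes 1000 --seed 7
```

generates a 1000-gene synthetic study at the observed category proportions,
runs every stage, and prints the category percentages:

```json
{
  "yome": 34.6,
  "well_annotated": 60.6,
  "excluded": 4.8
}
```

`readme_demo/summary.json` holds the full report. For this run: 346 y-ome,
606 well-annotated and 48 excluded genes (24 of the y-ome flagged
no-information); the planted 2-log2-unit expression deficit of y-ome genes
is detected with Welch *t* = −28.9 (p below double precision, i.e. far
below 10⁻⁶); the terminus/ORI density ratio is 148 for y-ome genes versus
0.91 for well-annotated genes, reflecting the planted terminus bias; and 76
y-ome genes co-occur with 181 well-annotated genes across the 12 generated
co-expression modules, yielding 76 ranked characterization candidates.
Outputs also include `categories.tsv` (the per-gene category table),
`term_frequency.tsv`, `yname_crosstab.tsv`, `chromosome_density.tsv` and
`candidate_genes.tsv`.

The same stages are available as library functions
(`yome.kb_ingest`, `yome.categorize`, `yome.consensus`,
`yome.expression`, `yome.chromosome`, `yome.coexpression`, `yome.terms`,
`yome.crosstab`) and as individual CLI subcommands
(`ingest`, `categorize`, `consensus`, `analyze-expression`,
`analyze-chromosome`, `analyze-modules`, `term-freq`, `crosstab`, `synth`).

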