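# Methods

## Problem and approach

Knowledge bases record gene annotations of very uneven depth, and none of
them directly states whether a gene has experimental evidence of function
with a mechanistic link to phenotype. The workflow therefore takes a
heuristic, reproducible approach: per-source categorization by keyword and
structured rules, followed by cross-source consensus with a small number of
high-trust exceptions, followed by manual overrides where sources genuinely
disagree. The final output is a partition of the unique-gene registry into
three categories — y-ome, well-annotated, excluded — plus a
no-information flag on the most data-poor y-ome genes.

## Gene identity resolution

Fragments from different sources merge by locus tag first, then by exact
primary-name match, then by synonym match (all case-insensitive for
names). Locus tags are the only stable cross-source key, so when two
sources give one locus tag different primary names the first-seen name is
kept and the other demoted to a synonym. Genes present in only one source
stay in the registry; the consensus layer handles their sparsity (a single
definite vote is agreement; none defaults to the y-ome with a
low-confidence flag, since absence of evidence is the y-ome's definition).

## Categorization rules

Keyword rules are data-driven configuration (`yome/data/default_rules.yaml`),
matched case-insensitively, substring by default with a word-boundary mode
per rule (keywords such as "predicted" appear inflected inside longer
descriptions, so substring is the safer default). The shipped defaults
cover the documented per-source indicator terms; real deployments are
expected to extend the file, which is why the engine is configuration-driven
rather than hard-coded. Structured rules: UniProt annotation scores map
≤ 2 → y-ome, 3 → not enough information, ≥ 4 → well-annotated; reaction
equations, complex annotations and insertion elements (including `ins*`
gene names) → well-annotated; pseudogene/phantom flags and EcoGene
apostrophe-terminated names → excluded. Cryptic (phenotypically silent)
genes receive no special rule and therefore stay in the y-ome. Within one
source, fired rules resolve by the precedence excluded > well-annotated >
y-ome; nothing fired means "not enough information".

## Consensus

Evaluation order: (1) any excluded vote wins — pseudogenes and phantom
genes are a separate track that functional-evidence heuristics never
resurrect; (2)–(5) the four well-annotated exceptions (EcoCyc evidence
keywords, RegulonDB Strong evidence, EcoCyc+UniProt both well-annotated,
insertion elements); (6) agreement, defined as: all definite votes
identical with at least one definite vote; (7) disagreement → manual
override, else unresolved. Since exceptions (2)–(5) all output
well-annotated, their relative order affects only the recorded basis, never
the category. The recorded basis is the first rule that decided; exclusion
is recorded with basis `agreement` (the basis vocabulary has no separate
exclusion entry, and exclusion is a structural, not evidentiary, decision).
One consequence of the order is that EcoCyc evidence keywords outrank a
y-ome keyword in EcoCyc's own description of the same gene — curated
experimental evidence is treated as strictly more trustworthy than
free-text phrasing.

In strict mode (the default) unresolved genes without an override abort the
run with an actionable list; in permissive mode they fall into the y-ome
flagged low-confidence with basis `unresolved` preserved for inspection, so
the no-unresolved-output invariant holds for strict or fully-curated runs.

The no-information detector treats a gene as having no information when
every content-bearing feature in every source is empty, matches a stock
no-information phrase (configurable, matched as lowercase substrings), is a
domain/family-only annotation, or is an annotation score ≤ 2. Genes
annotated only with a protein domain are kept in the y-ome *and* the
no-information list, because such domains typically carry no functional
information themselves.

## Expression

TPM is computed from counts in-repo by the standard definition
(length-normalized rates scaled to 10⁶ per sample); this is a deliberate
substitution for pipeline-specific upstream quantification, which is out of
scope. Replicate QC removes a condition's whole replicate group when its
minimum pairwise R² (squared Pearson correlation of log₂(TPM+1) across
genes) falls below 0.9 — group-wise removal is the conservative reading of
"replicates below threshold are removed". Per-gene mean expression averages
replicates within condition first, then across conditions (conditions, not
samples, are the unit of observation). The category contrast is a Welch
(unequal-variance) two-sample t-test. The top-expression threshold uses
numpy's linear-interpolation percentile convention (pinned and documented
because the convention changes the threshold on small samples; genes
*strictly above* the threshold form the top set).

## Chromosome density

Start coordinates are 1-based on the forward-numbered circular chromosome;
only start sites are used, so strand is ignored. Angles are
2π·(start−1)/L. The density estimator is a von Mises-kernel KDE evaluated
on a 1024-point grid; κ defaults to 50, corresponding to a kernel standard
deviation of ≈ 1/√50 rad ≈ 100 kb-scale smoothing on a 4.6-Mb chromosome —
the bandwidth is a free parameter, so density shapes should be read
qualitatively. The implementation uses exponentially scaled Bessel
functions so large κ stays finite, κ = 0 reduces exactly to the uniform
density 1/(2π), and every returned density is checked non-negative and
normalized (periodic trapezoidal integral within 10⁻⁶). ORI defaults to
the documented replication-origin coordinate of the E. coli K-12 reference
assembly with the terminus at its antipode; enrichment is the fraction of a
category's genes within a π/4-wide window around each landmark and their
terminus/ORI ratio (undefined, not infinite, when the ORI window is empty).

## Synthetic data

The generator emulates the study's structure with planted truth:

* **Categories.** Default fractions are the observed proportions
  (1600/2803/220 of 4623), apportioned by largest remainder so planted
  counts are exact at any n. Default no-information rate 111/1600 of y-ome
  genes. 71% of y-ome genes get 'y' primary names and 6% of well-annotated
  genes do, emulating the observed drift between naming and annotation.
* **Features.** Well-annotated genes receive one of five evidence
  mechanisms (assay evidence, high annotation score, reaction equation,
  strong TF evidence, or EcoCyc+UniProt agreement); y-ome genes receive
  low-annotation keywords or low scores; no-information genes receive only
  stock phrases and domain-only entries; excluded genes receive
  pseudogene/phantom flags or apostrophe names. Conflict-injected genes
  receive contradictory definite votes in two sources plus a generated
  override carrying the true label, so recovery through the manual layer is
  exact by construction.
* **Expression.** Per-gene expected log₂ expression ~ Normal(μ_cat, 1)
  with μ_yome = μ_well − δ (default δ = 2; excluded genes share the y-ome
  mean); 78 conditions × 2 replicates; replicate noise σ (default 0.2 log₂
  units, typical technical noise giving replicate R² ≈ 0.94) is added per
  sample and counts are rounded length-scaled powers of two — a lognormal
  shortcut, not a negative-binomial read simulator, sufficient for the
  category-contrast statistics exercised here. At stress-test noise
  (σ = 1) replicate R² drops to ≈ 0.4 and the QC stage correctly removes
  everything, so contrast-recovery checks at that noise evaluate the means
  without the QC stage.
* **Positions / modules.** Y-ome starts are von Mises-distributed around
  the terminus (default κ = 2), others uniform, all distinct integers.
  Modules have ≥ 10 members with a configurable y-ome mixing fraction.

All generators are deterministic under a fixed seed (byte-identical
files). What passing tests show is that the rules, consensus logic and
statistics behave exactly as specified on data whose generating process is
known; they do not show that the shipped keyword lists are complete for any
real knowledge-base release, that real expression compendia meet the QC
threshold, or that real positional enrichment is as clean as the planted
bias.

## Numerical choices

* Percentages are rounded half-up to one decimal (1600/4623 → 34.6); note
  220/4623 = 4.759% rounds to 4.8 under this rule.
* Percentile thresholds use numpy's default linear interpolation.
* Identical expression groups return t = 0, p = 1 rather than NaN.
* Ranking ties break by gene identifier, making candidate lists total
  orders invariant to input row order.
* Seeds: every generator takes one integer seed; sub-streams are derived
  by fixed offsets.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: KB
suites of 120–1000 genes (the acceptance script uses the full 4623),
expression compendia of 600 genes × 78 conditions × 2 replicates across
100–200 seed replications, 2000-gene position sets, and 12-module
assignments. These sizes make every stochastic check stable while keeping
runs to seconds.

## Known limitations

* Shipped keyword lists cover only the documented indicator terms; real
  releases need extended rule files.
* The canonical feature-table TSV is the ingestion contract; adapters for
  native knowledge-base dump formats are out of scope apart from
  GenBank/GFF3 gene positions.
* Co-expression module detection is consumed, not implemented.
* The KDE bandwidth is unstated by any source, so density-derived
  statements are qualitative; enrichment ratios depend on the window
  width.
* Manual-override content is user-supplied; the package only provides the
  mechanism and its audit trail.
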