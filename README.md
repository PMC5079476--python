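# seqcorr

Compare a sequencing experiment against a reference compendium, genome-wide,
by correlation.

A single RNA-seq, ChIP-seq or CAGE experiment is hard to interpret in
isolation: is the sample what its label claims, which public cell types does
it resemble, is it an outlier among nominal replicates? `seqcorr` answers
these questions by projecting a user sample into the feature space of a
pre-built reference compendium — a genes × experiments or genomic-regions ×
experiments matrix assembled from many reference experiments — computing the
Pearson correlation against every reference column, and exporting ranked
correlation tables and clustered correlation heatmaps. It is an offline
library plus CLI aimed at experimental groups who have processed output
(FPKM/TPM tables, peak BED files) but no downstream pipeline.

## Method

Three compendium kinds are supported, one per assay:

* **expression** — gene × experiment matrix of log-scaled abundances,
  entry = log₂(FPKM + 1) (base and pseudocount configurable);
* **peaks** (ChIP-seq) — region × experiment **binary** matrix: entry
  (r, s) = 1 iff experiment *s* has a peak overlapping region *r* by ≥ 1 bp.
  The region universe is the union of all reference peak sets with
  overlapping-or-bookended intervals merged, and is frozen at build time;
* **cage** — region × experiment matrix of log₂(summed tag expression + 1)
  per region.

A user sample is projected onto the compendium's feature index (genes
matched after case-folding and version-suffix stripping; peaks binarized
over the frozen universe) and compared to each reference experiment *s* by
the Pearson product-moment coefficient

r(x, y) = Σᵢ(xᵢ − x̄)(yᵢ − ȳ) / √(Σᵢ(xᵢ − x̄)² · Σᵢ(yᵢ − ȳ)²),

which on binary peak vectors equals the phi coefficient. Zero-variance
vectors yield an explicitly *undefined* correlation (exported as `NA`),
never a fabricated 0. For heatmaps, experiments are ordered by agglomerative
hierarchical clustering on the correlation distance d = 1 − r (complete,
average, single or ward linkage; deterministic lowest-index tie-breaking).
Metadata attached to every experiment (cell type, factor, source, …) allows
subsetting a compendium before correlating.

Coordinates are BED conventions throughout: 0-based, half-open.

## Worked example

Build a synthetic expression compendium of 5 cell-type groups × 4
experiments with planted correlation structure (within-group ρ = 0.8,
between-group ρ = 0.1), then compare a degraded copy of one group-3
experiment against it:

```sh
seqcorr synth --type expression --features 2000 --groups 5 --per-group 4 \
              --seed 1 --out ex/data
seqcorr build --type expression --manifest ex/data/samples.tsv \
              --metadata ex/data/metadata.tsv --out ex/comp
seqcorr compare --compendium ex/comp --expression ex/user.tsv \
                --out-table ex/table.tsv --out-heatmap ex/heatmap.png
```

where `ex/user.tsv` is `expr_group3_rep1` with 15 % of its gene values
shuffled (`seqcorr.perturb_sample`). The run logs
`projection: 2000/2000 features matched, 2000/2000 user items matched` and
the top of the ranked table reads:

```
experiment_id      r           group
expr_group3_rep1   0.8700912   group3
expr_group3_rep2   0.69727174  group3
expr_group3_rep4   0.69285946  group3
expr_group3_rep3   0.69100213  group3
expr_group5_rep4   0.13701185  group5
```

The degraded sample still correlates most strongly with its own source
(r = 0.87) and then with the other group-3 replicates at roughly the
planted within-group level, while every other group sits near the planted
between-group level — exactly the quality-control readout the tool exists
for. `ex/heatmap.png` shows the 21 × 21 clustered correlation heatmap with
the user sample highlighted.

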