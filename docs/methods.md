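# Methods

## Problem and model

`seqcorr` quantifies the similarity of one genome-wide experiment to each
member of a reference compendium. All comparisons reduce to the Pearson
product-moment correlation of two vectors in a shared feature space; the
whole design therefore revolves around making that feature space identical
between the user sample and every reference column.

**Expression.** Features are normalised gene identifiers (case-folded,
trailing `.N` version suffix stripped — the dominant cause of spurious
zero-overlap between Ensembl-style tables). The matrix entry is
log_b(value + c). Defaults b = 2, c = 1: FPKM/TPM values are zero-inflated,
so a pseudocount is required for finiteness, and log₂(x+1) is the field's
convention. The pseudocount is constrained to ≥ 1 so entries stay
non-negative. Genes absent from one sample are raw 0 (below any detected
gene after transform), not dropped: dropping would change the feature space
per sample and make correlations incomparable.

**Peaks.** Features are the *region universe*: the union of all reference
peak sets, with overlapping **or bookended** intervals merged. Merging
bookended intervals keeps the universe canonical (no two adjacent regions
that are indistinguishable from one region at ≥ 1 bp overlap resolution).
Entry (r, s) = 1 iff some peak of experiment s overlaps region r by ≥ 1 bp,
with half-open semantics (overlap iff max(starts) < min(ends)); the Pearson
coefficient of two such columns is the phi coefficient. The 1 bp threshold
is the permissive default; nothing in the pipeline depends on its exact
value.

**CAGE.** Same universe construction from the scored peak files; entry
(r, s) = log_b(sum of scores of experiment-s intervals overlapping r + c).
Sum-then-log, not log-then-sum, so splitting one tag cluster into two
intervals does not change the entry.

**Frozen universe.** The universe (and the gene list) is fixed when the
compendium is built. User samples are projected onto it and can never
extend it; user-only genes/peaks are dropped and counted in a coverage
report. Consequence: reference-vs-reference correlations are invariant to
whatever the user uploads, and a cached compendium is valid indefinitely.

**Undefined correlations.** A zero-variance vector (all-zero projected peak
sample, constant expression column) has no Pearson coefficient. It is
reported as undefined (NaN internally, `NA` in exports), ranked last, and
excluded from clustering — reporting 0 would fabricate a rank for a sample
that carries no signal.

## Clustering and display order

Experiments are ordered by agglomerative clustering on d = 1 − r (range
[0, 2]; anti-correlated samples maximally distant). Four linkages are
exposed: complete (default — the common heatmap default and robust to
chaining), average, single, ward (Lance–Williams recursion on d). The merge
loop is implemented in the package rather than delegated so that
tie-breaking is part of the contract: among equidistant pairs the one whose
clusters contain the lowest original indices merges first, the merged
cluster keeps the position of its lowest-index member, and the lower-index
cluster becomes the left dendrogram child. This makes leaf orders
bit-reproducible across runs and platforms (the test suite independently
checks the merge heights and nested partitions against SciPy's `linkage`).
Undefined-correlation experiments are appended after the clustered leaves
in original order. Merge heights are not forced monotone (ward on an
arbitrary dissimilarity can produce inversions; the dendrogram renders them
as-is).

## Rendering and export

Heatmaps use a diverging map on the fixed domain [−1, 1] — never rescaled
to the data — so every figure shares one colour key. Undefined cells are
drawn in grey (`#b0b0b0`). Labels auto-hide above 80 experiments
(configurable). SVG output uses a fixed `svg.hashsalt` and all formats
suppress embedded creation timestamps, so identical runs produce identical
bytes. Tables are TSV/CSV with 8 significant digits and literal `NA` for
undefined values; re-reading an exported table reproduces ranks exactly.
Figure formats: png, svg, pdf; rendering is exercised up to 500 × 500,
which covers a realistically subset compendium (full public compendia are
viewed after metadata subsetting).

## Synthetic compendia

The generators produce miniature compendia with *planted* correlation
structure so that recovery properties can be asserted against ground truth.
Default design: 5 groups × 4 experiments, ρ_in = 0.8, ρ_out = 0.1, 2000
features, genome model of 3 chromosomes × 10 Mb (small enough for per-base
brute-force oracles). These defaults are the study conditions used by the
acceptance tests and `scripts/acceptance.py`.

**Expression.** Log₂ profile of experiment e in group g:
z_e = μ + σ·(√ρ_out·G + √(ρ_in−ρ_out)·H_g + ν·√(1−ρ_in)·ε_e) with
independent standard-normal latents G (global), H_g (per group), ε_e (per
experiment), μ = 4, σ = 1.5 (log₂ FPKM scale), noise multiplier ν = 1.
Expected pairwise correlation is exactly ρ_in within and ρ_out between
groups at ν = 1; a ν that moves the expectation more than 0.1 from the
targets raises `InfeasibleDesignError` instead of drifting. Values are
exponentiated back to FPKM-like numbers via 2^z − 1 (clipped at 0, which
touches ~0.4 % of genes at the defaults) and rounded to 6 decimals so a
written table re-reads identically. Latents and noise are keyed by
(seed, group, replicate) `SeedSequence`s: enlarging a design with extra
replicates leaves existing experiments untouched, which is how held-out
user samples are drawn from a group.

**Peaks.** Universe regions come in three kinds: characteristic of exactly
one group (retained by members with probability p_hi, by nobody else),
shared (p_hi for everyone), and background (low p_lo for everyone). A
region not retained by any experiment never enters the built universe, so
the observable phi coefficients are *conditional* on retention-by-someone.
The kind weights and p_hi are solved numerically (weighted least squares on
the closed-form conditional moments) so that the conditional within- and
between-group phi equal ρ_in and ρ_out; the marginal peak density (default
target 0.2) is matched as closely as the remaining degrees of freedom
allow. A residual above 0.02 on either phi target raises
`InfeasibleDesignError`. Realized values at the default design land within
~0.01 of targets (reported by the acceptance script). An explicit
`retention_probs=(p_member, p_other)` bypasses the solve with a plain
partition model — (1, 0) gives identical peak sets within a group and zero
sharing across groups, the deterministic limit used in tests. Regions are
200 bp wide on a 1 kb grid, so distinct master regions never merge.

**CAGE.** Peak-model presence with log-normal scores around a shared
per-region base intensity (base ~ N(5, 1.5²) in log₂, experiment-level
spread 0.5), rounded to 4 decimals for exact BED round-trips.

**Perturbation.** `perturb_sample` degrades a sample for outlier/QC
scenarios: a fraction *intensity* of gene values is shuffled among
themselves (expression) or of peaks relocated uniformly on the genome model
(peaks). Intensity 0 is the identity; expected correlation with the source
decreases monotonically in intensity (≈ 1 − intensity for expression, since
a shuffled fraction contributes zero expected covariance).

What the generators do **not** emulate: library-size and batch effects,
heavy-tailed count noise, peak-width and chromatin-accessibility structure,
genome-scale region counts, or the metadata heterogeneity of real public
compendia. Passing recovery tests therefore demonstrate correctness of the
pipeline's bookkeeping and statistics under controlled correlation
structure, not performance on real public data.

## Numerical choices

* Pearson is computed from centred dot products in float64; the result is
  clipped to [−1, 1] and a bitwise-identical input pair returns exactly 1.0
  (guarding against a 1-ulp wobble in `sqrt(t·t)`).
* Compendium matrices are serialised with 17 significant digits
  (`%.17g`), making the text round-trip bit-exact for float64.
* Correlation requires vector length ≥ 3 and ≥ 2 experiments; degenerate
  inputs raise data errors rather than returning vacuous results.
* Duplicate gene ids keep the maximum value (deterministic and
  order-independent) with a logged warning.

## Problem sizes

The test suite and acceptance script run on compendia of 20–25 experiments
× 300–2000 features, 100-seed Monte Carlo loops for rate estimates, and
oracle comparisons on 200 random interval instances and 10⁴ vector pairs —
sizes chosen so the whole verification cycle completes in well under a
minute while keeping every rate estimate's Monte Carlo error far below the
asserted margins.

## Known limitations

* No cross-annotation gene-id translation (symbol ↔ Ensembl) and no
  coordinate liftover; inputs must share the compendium's annotation.
* No normalisation beyond the log transform (no quantile/library-size
  correction) — compendia are only as comparable as their upstream
  processing.
* Undefined correlations make a sample invisible to clustering rather than
  imputing a similarity.
* The naive O(n²)-per-merge clustering is comfortable to ~1000 experiments;
  larger compendia should be subset by metadata first.
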