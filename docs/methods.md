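# Methods

## Problem

Single-cell transcriptomic studies of sprouting angiogenesis produce long
ranked lists of putative tip endothelial-cell (tip EC) markers, far more
than any laboratory can validate functionally. This package implements the
in-silico half of that problem: combine several datasets' marker rankings
into one congruence ranking, score each candidate's specificity for the tip
cluster in a labeled tumor-microenvironment atlas, and walk the result
through a GOT-IT-style assessment-block cascade to a short list of
candidates, each with an auditable verdict. A second layer provides the
statistics used to quantify the downstream validation assays.

## Rank-product congruence meta-analysis

Each of K datasets contributes a scored gene list; within a list, rank 1 is
the highest score, ties receiving average ranks (midranks), so the rank
multiset of an n-gene list always sums to n(n+1)/2. For a gene g with rank
r_{g,d} in dataset d, the rank product is

    RP_g = prod_d r_{g,d}

Small RP means consistent top ranking. By default only genes present in all
K lists are housed (intersection policy); a worst-rank imputation (rank =
n_d for a missing gene) is available behind an explicit flag for users who
prefer the union, at the cost of a pessimistic bias against partially
observed genes.

Significance uses the standard rank-product null: each gene's rank is
independently uniform on {1..n_d} per dataset, and p = P(RP_null <= RP_obs).
Cross-gene dependence of ranks within a dataset (ranks are a permutation,
not independent draws) is deliberately ignored — the usual approximation
for this statistic, adequate when the number of genes is large relative to
the planted signal. Two evaluation modes:

* **enumerate** — exhaustive enumeration of all prod(n_d) rank tuples,
  allowed up to 10^6 tuples; exact.
* **montecarlo** — B sampled tuples (default B = 100,000, minimum 1000)
  with the add-one correction p = (b+1)/(B+1), so p ∈ [1/(B+1), 1] and a
  Monte-Carlo p is never zero. A seed is mandatory; there is no hidden RNG
  state anywhere in the package.

The product itself is taken directly in double precision (exact for
integer-valued ranks up to 2^53) with a log-space fallback if the direct
product overflows; the geometric mean RP^(1/K) is always computed in log
space. Multiple testing uses Benjamini–Hochberg step-up FDR over all tested
genes. BH is the correction implemented — no Storey-type q-value estimator
is offered, to keep one well-defined correction on the surface.

## Marker specificity (the logFC > 1 rule)

The atlas is a cells × genes matrix of raw non-negative integer counts with
one cluster label per cell. Library-size normalization maps a count c in a
cell with total T to ln(1 + s·c/T) with s = 10^4. The specificity contrast
is the target cluster versus **all other cells pooled** (not one-vs-each),
with clusters larger than `max_cells_per_cluster` (default 1000) subsampled
without replacement under the caller's seed; subsampling is order-invariant
because candidate indices are sorted before sampling.

Per gene:

* logFC = ln((m_in + 1)/(m_out + 1)), where m is the mean over cells of
  expm1(normalized value) inside/outside the target cluster. Natural log
  throughout; the +1 pseudocount on both means keeps the ratio finite when
  a gene is silent on one side and is the documented convention here.
* pct_in / pct_out = fraction of cells with count > 0, which is therefore
  independent of normalization.
* A one-sided (greater) Wilcoxon rank-sum p-value on normalized values,
  assigned only to genes with positive logFC ("positive markers only");
  midranks with tie correction at large n, exact enumeration for small
  tie-free groups (scipy's method selection). BH q over the tested set.

The specificity rule passes a gene iff logFC > 1 **strictly**; logFC = 1.0
fails. A gene absent from the matrix gets verdict `unknown`, never a silent
pass.

## The assessment-block cascade

Four blocks are evaluated per gene over the top-50 of the congruence
ranking (AB3 concerns microbial targets and is skipped by construction):

| block | fails when | granularity |
|---|---|---|
| AB1 | the target phenotype's disease-condition fraction < 0.9 | phenotype-level |
| AB2 | an established genetic disease link in adults | per gene |
| AB4 | already described in tip cells, or ≥ 20 angiogenesis publications, or ≥ 3 tip-cell publications | per gene |
| AB5 | secreted product, or no perturbagen, or specificity rule fails | per gene |

AB1 is quantified from a phenotype × condition contingency table
(row-normalized fractions); the 0.9 default is configurable — the source
material reports the observed fraction (99.3 % of tip cells tumor-derived)
but names no cutoff, so the default is a conservative round figure below
that observation. Publication counts are trusted inputs; literature mining
is out of scope. All count thresholds are strict (`< 20`, `< 3`) to match
the stated selection wording.

Three-valued logic: annotation flags are `true`/`false`/`unknown`, and
`unknown` is never coerced to `false`. A gene with any unknown flag (or a
missing annotation row, or absence from the expression matrix) is excluded
with verdict `unknown` — the fail-safe stand-in for the manual review the
original selection performed per gene. `final_candidate` is true iff all
four blocks pass. The funnel report attributes each excluded gene to its
first failing block (AB1 → AB2 → AB4 → AB5 order) or to `unknown`, so the
counts always sum to top_n.

## Validation-assay statistics

* percent change = (1 − treated/control)·100; positive = reduction.
* wound closure = (gap_T0 − gap_T18)/gap_T0·100; negative closure (gap
  widened) is reported, not clamped.
* Tip competition: two-cell Pearson chi-square goodness-of-fit of
  (k, n−k) against (n·p0, n·(1−p0)) with p0 = 0.5, df = 1, upper-tail p,
  **no Yates continuity correction** (the plain two-cell convention);
  expected counts below 5 attach a warning flag rather than an error.
  Both per-set and pooled-across-replicates entry points exist, since the
  assay can be scored either way.
* Two groups: unpaired two-tailed Student t-test (equal variances) by
  default, Welch behind a flag. Zero pooled variance with unequal means
  reports p at the machine floor with a flag. Three or more groups: one-way
  ANOVA (F on (k−1, N−k) df) with Tukey HSD adjusted p-values from the
  studentized-range distribution.

## Synthetic-data generators

The generators exist so that every stage has inputs with known planted
truth; each is a pure function of its config (identical seed ⇒ identical
output) and serializes its truth next to the data.

* **Rank lists** — planted gene i targets position i, jittered by
  N(0, concordance_noise²) independently per dataset (default noise sd 5
  ranks on a 200-gene universe — enough that single-dataset rankings
  shuffle visibly while the congruent signal survives); non-planted genes
  fill the remaining positions exchangeably.
* **Expression** — counts ~ NB(mean, theta) with var = mu + mu²/theta,
  theta = 2 (typical droplet-scale overdispersion), a 1000-gene
  transcriptome with baseline mean 1 (mild lognormal gene-to-gene spread),
  planted markers raised to mean 3, and the planted fold multiplying the
  tip-cluster mean only. Marker expression is kept a small fraction of the
  per-cell library deliberately: if planted markers dominate the library,
  library-size normalization compresses the realized fold below the plant
  (a composition effect real atlases largely avoid because markers are a
  sliver of the transcriptome). Condition labels make tip cells tumor-
  derived with probability 0.993, matching the reported tip-cell tumor
  enrichment; other clusters are split 50:50.
* **Annotations** — profiles `all_pass`, `all_unknown`, and `paper_like`,
  the latter planting the six passing candidates (CD93, TCF4, ADGRL4, GJA1,
  CCDC85B, MYH9) and the named failure archetypes: SPARC and SEMA6B
  disease-linked (AB2), SMAD1 previously described in tip cells (AB4), and
  SOX4/FAM43A non-specific (AB5, via the companion specificity table);
  filler genes fail AB4 on publication counts.
* **Competition** — one tip per spheroid, k ~ Binomial(n, p_tip). The
  one-tip idealization reflects how the assay is scored (which genotype
  occupies the tip position), not spheroid biology.
* **Assays** — control ~ N(mu, (cv·mu)²) with cv = 0.15 (replicate-level
  variability typical of primary-cell assays), treated groups scaled by
  (1 − effect).

What the generators do **not** emulate: dropout beyond NB sampling, batch
and donor effects, ambient RNA, doublets, cross-gene correlation, or any
realistic assay error structure beyond i.i.d. Gaussian noise. Passing
tests therefore demonstrate correctness of the computations and
recoverability of planted signal under clean conditions — not performance
on real atlases.

## The end-to-end bundle

`tipselect.pipeline.generate_bundle` writes one coherent synthetic study: a
50-gene congruent panel (the six candidates first, then the archetypes,
then fillers) planted at the top of three rank lists with jitter sd 1; an
expression matrix (4 clusters × 150 cells, 2050 genes) planting fold e^1.5
for every panel gene except SOX4 (fold 1) and FAM43A (fold e^0.5); the
paper-like annotations; assay and competition tables; and truth.json. The
pipeline run on this bundle recovers exactly the six planted candidates,
with the archetypes excluded at their documented blocks.

## Numerical and determinism choices

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no generator reads global state.
* Output tables are written with a fixed `%.10g` float format, which (with
  seeded RNG) makes pipeline reruns byte-identical.
* Sorting ties break on gene_id lexicographically, everywhere.
* Rank-product enumeration is capped at 10^6 tuples; beyond that the code
  refuses and directs the caller to Monte-Carlo.
* Problem sizes in the test-suite recovery checks — 500 cells per cluster
  for fold recovery, B = 50,000 for the Monte-Carlo/enumeration agreement,
  10,000 replicates for test calibration — were chosen as the smallest
  sizes at which the sampling error of the checked quantity is comfortably
  inside the assertion tolerance.

## Known limitations

* The permutation null ignores within-dataset rank dependence (see above).
* The logFC > 1 rule is interpreted in natural-log units; toolkits using
  log2 would need lfc_min adjusted.
* No attempt is made to reproduce per-gene numbers from the original
  atlases; real-data mode consumes pre-downloaded files through the same
  readers but dataset-specific preprocessing is out of scope.
* Tukey HSD on groups with zero within-group variance yields an undefined
  (NaN) statistic, surfaced as-is.
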