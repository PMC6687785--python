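# Methods

## The synthetic cohort model

The generator (`tumormatch.simulate`) draws one tumor type at a time. Its
components, all on the linear (count-expectation) scale unless noted:

- **Baseline transcriptome.** Per-gene log2 abundance b_g ~ N(7, 1.5).
  The mean of 7 (median expected count ≈ 128) puts genes in the
  dispersion-dominated regime typical of bulk RNA-seq; at substantially
  shallower depth, per-gene Poisson noise varies with library size and
  leaks a spurious library-size signal into sample–sample correlations.
- **Subtypes.** Each of `n_subtypes` cancer profiles elevates its own
  `n_marker_genes_per_subtype` marker genes by `subtype_logfc` (default 2,
  i.e. 4-fold). Tumor and cell-line samples carry subtype labels
  round-robin.
- **Contamination.** A single immune/stromal profile elevates
  `n_immune_genes` immune genes by `immune_logfc` (default 3) over
  baseline; the cancer profiles *depress* the same genes by the same
  amount, because immune transcripts originate from infiltrating cells and
  are essentially absent from pure cancer-cell populations. This is what
  makes immune genes fail the "expressed in the top half of at least two
  cell lines" template filter, as they should.
- **Mixing.** A tumor with purity p (p ~ Beta(5, 2), mean ≈ 0.71) has
  expectation p·C_g + (1−p)·I_g, where C is its subtype's cancer profile
  and I the contamination profile. Cell lines are pure C with
  `n_proliferation_genes` proliferation genes elevated by
  `proliferation_logfc` (the in-vitro culturing signal).
- **Sequencing is compositional.** Each sample's expectation vector is
  rescaled to a common total before the library factor is applied:
  sequencing draws a fixed number of reads in proportion to relative
  abundance, so contamination dilutes cancer transcripts rather than
  adding depth. (Without this, immune content inflates library size and
  purity becomes confounded with depth — an artifact, not a property of
  real data.)
- **Batch.** A `batch_fraction` of tumor samples (second platform) gets an
  additive per-gene log2 shift ~N(0, `batch_sd`) on the log-mean.
- **Counts.** Negative binomial with a single global dispersion
  (`nb_dispersion`, default 0.1; variance μ + 0.1μ²) and log-normal
  library factors (`libsize_logsd` = 0.3 on the natural-log scale).

Default sizes (2000 genes, 100 tumors, 30 cell lines, 3 subtypes) run the
full pipeline in seconds; the three-replicate subtype benchmark uses 150
tumors. These are the problem sizes used throughout the tests and the
acceptance script.

**What the generator does not emulate:** gene–gene correlation beyond the
module structure, per-gene dispersions, isoform-level effects, multiple
contamination cell types, purity-estimation error (truth purity is exact),
and cohort sizes near the real compendia. Passing tests therefore
demonstrate correctness of the machinery and qualitative recovery of the
confounding structure, not quantitative agreement with any real cohort.

## Normalization

Upper-quartile scaling divides each sample by its 75th percentile of
*nonzero* counts (linear-interpolation "type 7" percentile), normalized so
the common target is the geometric mean of per-sample quartiles — making
the operation scale-free, order-independent and idempotent. The log
transform is log2(x + 1); neither the log base nor the pseudocount is
forced by anything upstream, so both are package defaults. Quantile
normalization maps every column onto the across-sample mean of sorted
values, with exact ties receiving the mean of the reference values their
ranks span.

## Batch correction

`combat_adjust` is the parametric empirical-Bayes location/scale model:
gene-wise standardization against the batch-size-weighted grand mean and
pooled variance, per-batch location/scale estimates shrunk toward
normal/inverse-gamma priors fit by method of moments, then adjustment and
de-standardization. Two deliberate numerical choices differ from the
common reference arithmetic: per-batch scale estimates use the same
denominator convention as the pooled variance (ddof = 0), so two
identical batches yield scale factors of exactly 1 and the adjustment is
the identity; and the output is re-centered per gene so the grand mean is
preserved exactly (the EB location adjustment preserves it only
approximately). Genes with zero pooled variance pass through untouched; a
single batch is an identity with a warning; a batch with fewer than two
samples is an error.

Shrinkage means the adjustment removes the *shared* part of the observed
batch gap and deliberately leaves a fraction of the gene-specific
deviation (mostly sampling noise). The residual gap scales with the
per-batch sampling error of the batch means, so effectiveness benchmarks
use batches large enough (50 samples, noise SD 0.5 against a planted
0.8 ± 0.1 shift) that the shared shift dominates.

## Purity adjustment

The filter computes the Pearson correlation of each gene's log-expression
with purity across tumors (Pearson, matching the linear regression that
follows) and removes genes with R ≤ −0.4 and BH-FDR < 0.01 — one-sided
toward the contamination direction, since immune/stromal content falls as
purity rises; a `two_sided` mode exists for symmetric filtering. The
regression step fits expr = a + b·purity per gene and replaces each value
with the fit evaluated at purity 1 plus the sample's own residual: a
location-only projection to the pure-tumor reference that leaves residual
variance untouched and makes tumors directly comparable to cell lines
(purity 1 by construction). Purity exactly 1 everywhere is a no-op rather
than an error.

Two small residual channels remain after adjustment, visible at desk
scale (|R| up to ~0.1 at n = 100) and present in principle in any cohort:
compositional dilution makes low-purity tumors slightly noisier on
cancer genes, and the pooled (across-subtype) regression under-corrects
marker genes whose purity slope is subtype-specific. Neither is removed
by the method, which is faithful to how the adjustment behaves on real
data.

## Differential expression

`voom_weights` computes logCPM = log2((count + 0.5)/(libsize + 1)·1e6),
quantile-normalizes it, fits each gene by OLS on the design, and smooths
sqrt-residual-SD against average log2 count with lowess (span 0.5, trend
floored at 1e-4); per-observation weights are the inverse fourth power of
the trend at the observation's fitted log-count. The design for the
tumor-vs-cell-line contrast is intercept + tumor indicator + purity, with
cell-line purity pinned at 1 and purity entered uncentered; positive LFC
means up in tumors, and flipping the coding flips every sign exactly.
Gene-wise WLS rescales weights to unit mean per gene, making coefficients
*and* s² invariant to a common weight rescaling. Moderation estimates
(d₀, s₀²) by matching the first two moments of log s² to the scaled-F
prior predictive (trigamma inversion by Newton); when log s² shows no
excess spread the prior df is infinite and the pooled arithmetic-mean
variance is used with a normal reference. DE calls require FDR < 0.01 and
|LFC| > 2.

## Preranked enrichment

Classic (unweighted) scoring: +1/|S| per hit, −1/(N−|S|) per miss; ES is
the maximum-magnitude deviation of the running sum, computed in closed
form at the hit positions so the observed and permutation paths share
bitwise-identical arithmetic. When the positive and negative extremes tie
exactly, the positive one is reported. The null is gene-set resampling
(the only choice for a preranked list), cached per intersection size;
NES = ES / mean(|null ES| of matching sign); the nominal p is the
same-sign tail fraction; FDR is the ratio-of-tails rule on the pooled
sign-matched NES null, made monotone in |NES|. Ranking ties break by gene
ID so results are reproducible.

## Nearest-template classification

Templates are binary indicator vectors over the union of marker genes;
expression is gene-standardized across the cohort being classified (so a
global affine shift of all samples cannot influence calls, and tumors and
cell lines are each standardized within their own cohort); distance is
cosine (a correlation-distance option exists). Genes qualifying for
several subtypes go to the one with the largest LFC. Significance: the
nominal p is the +1-smoothed fraction of `n_resample` (default 1000)
random same-size gene sets achieving a distance at most the observed one,
so p is never 0; BH-FDR is taken across samples and a call is assigned
iff FDR ≤ 0.05. Distance ties break by subtype name. Accuracy on the
held-out tumors counts unassigned samples as errors — the stricter
convention — and the 80% gate must pass before cell lines are classified.

## Panels

Selection is a deterministic function of the summaries and calls: ties
break by cell-line ID everywhere. The subtype-diverse rule visits
subtypes by prevalence among assigned calls (most prevalent first) when
slots are scarce, then fills remaining slots by overall median ρ. No
minimum-correlation floor is applied for inclusion.

## Small-sample statistics

Rank-sum tests use exact enumeration for tie-free groups of ≤ 20 and the
tie-corrected normal approximation otherwise. Quartile membership uses
the same type-7 percentile convention as normalization, with boundary
values going to the middle group (excluded from both extremes). The
subtype-proportion comparison is a Pearson chi-squared without continuity
correction, warning when any expected count is below 5.

## Known limitations

- The signature purity estimate is a z-score average mapped affinely to a
  configured range — a monotone proxy adequate for synthetic cohorts, not
  a calibrated substitute for consensus purity estimation on real data.
- The cross-tumor-type median matrix needs a shared gene universe; with
  per-type variable-gene lists the intersection convention is recorded in
  the output metadata.
- ComBat supports parametric priors only (no nonparametric mode, no
  reference batch).
- The DE engine supports the two-group + purity design and one-vs-rest
  contrasts; arbitrary contrast matrices are out of scope.
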