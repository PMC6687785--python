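# tumormatch

Cancer cell lines are routinely used as stand-ins for the tumors they were
derived from, but they vary widely in how faithfully they preserve the
primary tumor's transcriptome. Comparing a cell line's expression profile
with bulk tumor profiles is confounded by **tumor purity**: bulk tumors
contain immune and stromal cells that pure cultures lack, so low-purity
tumors look systematically less like every cell line. `tumormatch`
implements a purity-aware pipeline for scoring cell lines as transcriptomic
models of primary tumors, classifying them into tumor molecular subtypes,
and assembling representative cell-line panels — together with a
synthetic-cohort generator that provides ground-truthed inputs so every
stage can be validated without external downloads.

## What it computes

**Fidelity scoring.** Counts are upper-quartile normalized, log2
transformed and (when two sequencing platforms are mixed) batch-corrected
with a parametric empirical-Bayes location/scale model (ComBat). Genes
whose log-expression is strongly *negatively* correlated with purity
(Pearson R ≤ −0.4, BH-FDR < 0.01 — the contamination signature) are
removed, and each remaining gene is projected to a pure-tumor reference by
per-gene linear regression evaluated at purity 1, the implicit purity of a
cell line. Over the 5000 most variable genes (interquartile range across
tumors), the pipeline computes the Spearman correlation ρ between every
cell line and every tumor; a cell line's fidelity score is its median ρ.
Diagnostics quantify the purity confounder before/after adjustment: the
pooled Pearson association between ρ and tumor purity, and a one-sided
rank-sum test of ρ against top- versus bottom-purity-quartile tumors.

**Differential expression and enrichment.** Tumor-vs-cell-line contrasts
use count precision weights (the voom mean–variance trend), gene-wise
weighted least squares with purity as a covariate (cell lines pinned at
purity 1), and empirical-Bayes moderated t statistics with the posterior
variance s̃² = (d₀s₀² + d·s²)/(d₀ + d). Ranked by log2 fold change, gene
sets are scored with classic (unweighted) preranked enrichment: the ES is
the maximal running-sum deviation, normalized against size-matched random
gene sets, with ratio-of-tails FDR.

**Subtype classification.** A modified nearest-template workflow:
stratified 80/20 tumor split; one-vs-rest moderated DE on the training set
defines per-subtype template genes (LFC > 1, FDR < 0.01); templates are
filtered to cell-line-relevant genes (tumor-vs-cell-line |LFC| ≤ 2 and
expressed in the top half of at least two cell lines); samples are called
by cosine distance between their standardized profile and binary subtype
templates, with significance from random gene-set resampling and BH-FDR
across samples (assigned iff FDR ≤ 0.05). Cell lines are classified only
if held-out tumor accuracy reaches 80%.

**Panels.** Fixed-composition panels take the top cell lines per tumor
type by median ρ; the subtype-diverse variant (5 lines × 22 types = 110)
first covers each assigned subtype with its best line. Panels are compared
by a rank-sum test on per-line median ρ.

## Worked example

```python
from tumormatch import fidelity
from tumormatch.pipeline import run_fidelity, run_subtype_workflow
from tumormatch.simulate import SyntheticConfig, generate_cohort

counts, metadata, truth = generate_cohort(SyntheticConfig(seed=1))

unadj = run_fidelity(counts, metadata, adjust_purity=False)
adj = run_fidelity(counts, metadata, adjust_purity=True)
r0, _ = fidelity.purity_correlation_association(unadj.correlation, truth.purity)
r1, _ = fidelity.purity_correlation_association(adj.correlation, truth.purity)
print(f"rho~purity association: R={r0:.2f} (unadjusted) -> R={r1:.3f} (adjusted)")

print(adj.summary.head(3).round(3).to_string())

res = run_subtype_workflow(counts, metadata, seed=1)
print(f"held-out subtype accuracy: {res.test_accuracy['accuracy']:.2f}")
```

prints

```
rho~purity association: R=0.95 (unadjusted) -> R=0.001 (adjusted)
           median_rho  sd_rho  rank
cell_line
CL028           0.884   0.009     1
CL025           0.880   0.010     2
CL005           0.878   0.009     3
held-out subtype accuracy: 1.00
```

The unadjusted run shows the purity confounder at full strength — cell
lines correlate far better with high-purity tumors — and the adjustment
removes it almost entirely. The summary ranks cell lines by median ρ
against their tumor cohort (higher = more faithful model); the small SDs
indicate that between-line differences dominate within-line spread. The
subtype workflow recovers the planted subtype structure and passes the
accuracy gate, so the cell lines are classified.

The same stages are available from the shell:

```
tumormatch simulate --out sim --seed 1
tumormatch correlate --counts sim/counts.tsv --metadata sim/metadata.tsv --out fid
tumormatch subtype   --counts sim/counts.tsv --metadata sim/metadata.tsv --out sub --seed 1
tumormatch run-all   --out all --seed 1
```

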