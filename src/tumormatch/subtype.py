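"""Nearest-template subtype classification adapted to cell lines.

Workflow: stratified 80/20 split of labeled tumors; one-vs-rest
differential expression on the training set to pick template genes
(up-regulated, LFC > 1, FDR < 0.01); removal of template genes that
differ strongly between tumors and cell lines (|LFC| > 2) or are weakly
expressed in cell lines (not in the top half of expression in at least
two lines); nearest-template classification by cosine distance between a
sample's standardized profile and binary subtype templates, with
significance from size-matched random gene sets and BH-FDR across
samples; an accuracy gate on the held-out tumors before the templates
are applied to cell lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffexp import call_de, ebayes_moderate, fit_weighted_lm, voom_weights
from .fidelity import CorrelationMatrix, summarize_cell_lines

logger = logging.getLogger("tumormatch")

__all__ = [
    "SubtypeTemplateSet",
    "split_train_test",
    "build_templates",
    "filter_templates_for_cell_lines",
    "ntp_classify",
    "evaluate_accuracy",
    "subtype_proportion_test",
    "subtype_specific_ranks",
]


@dataclass
class SubtypeTemplateSet:
    """Per-subtype marker-gene templates with filter provenance."""

    templates: dict[str, list[str]]
    provenance: pd.DataFrame  # gene, subtype, status
    n_resample: int = 1000
    seed: int = 0
    source_split: str = ""

    @property
    def subtypes(self) -> list[str]:
        return sorted(self.templates)

    @property
    def union(self) -> list[str]:
        out: list[str] = []
        for s in self.subtypes:
            out.extend(self.templates[s])
        return out


def split_train_test(
    sample_ids: list[str],
    labels: pd.Series,
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified random split; every subtype lands in both partitions."""
    labels = labels.loc[sample_ids]
    counts = labels.value_counts()
    singletons = sorted(counts.index[counts < 2])
    if singletons:
        raise ValueError(f"subtypes with a single sample cannot be split: {singletons}")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for subtype in sorted(counts.index):
        members = [s for s in sample_ids if labels[s] == subtype]
        perm = rng.permutation(len(members))
        n_train = int(round(train_frac * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)  # both sides non-empty
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


def build_templates(
    train_counts: pd.DataFrame,
    labels: pd.Series,
    lfc_cutoff: float = 1.0,
    fdr_cutoff: float = 0.01,
    n_resample: int = 1000,
    seed: int = 0,
) -> SubtypeTemplateSet:
    """One-vs-rest moderated DE per subtype; up-regulated passers become
    that subtype's template. A gene qualifying for several subtypes goes
    to the one with the largest LFC only."""
    labels = labels.loc[train_counts.columns]
    subtypes = sorted(labels.unique())
    if len(subtypes) < 2:
        raise ValueError("need >=2 subtypes to build templates")
    candidate_lfc: dict[str, dict[str, float]] = {}
    for subtype in subtypes:
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "group": (labels == subtype).astype(float),
            },
            index=train_counts.columns,
        )
        y, w = voom_weights(train_counts, design)
        fits = fit_weighted_lm(y, w, design, contrast="group")
        table = call_de(ebayes_moderate(fits), lfc_cutoff=lfc_cutoff, fdr_cutoff=fdr_cutoff)
        up = table[(table["fdr"] < fdr_cutoff) & (table["lfc"] > lfc_cutoff)]
        if up.empty:
            raise ValueError(
                f"no template genes for subtype {subtype!r}; "
                "lower cutoffs or inspect the data"
            )
        candidate_lfc[subtype] = up["lfc"].to_dict()
    # resolve genes claimed by several subtypes: keep the largest LFC
    assignment: dict[str, str] = {}
    for subtype in subtypes:
        for gene, lfc in candidate_lfc[subtype].items():
            if gene not in assignment or lfc > candidate_lfc[assignment[gene]][gene]:
                assignment[gene] = subtype
    templates = {
        s: sorted(g for g, sub in assignment.items() if sub == s) for s in subtypes
    }
    empty = [s for s, genes in templates.items() if not genes]
    if empty:
        raise ValueError(f"subtypes lost all template genes to conflicts: {empty}")
    prov = pd.DataFrame(
        [(g, s, "kept") for s in subtypes for g in templates[s]],
        columns=["gene", "subtype", "status"],
    )
    return SubtypeTemplateSet(
        templates=templates, provenance=prov, n_resample=n_resample, seed=seed
    )


def filter_templates_for_cell_lines(
    templates: SubtypeTemplateSet,
    tumor_vs_cl_de: pd.DataFrame,
    cell_x: pd.DataFrame,
    lfc_cutoff: float = 2.0,
    min_cell_lines: int = 2,
) -> SubtypeTemplateSet:
    """Keep template genes that behave comparably in cell lines.

    Drops a gene if its tumor-vs-cell-line |LFC| exceeds ``lfc_cutoff``,
    or if it is not in the top half of expression (at or above that
    sample's across-gene median) in at least ``min_cell_lines`` lines.
    """
    medians = cell_x.median(axis=0)
    rows = []
    filtered: dict[str, list[str]] = {}
    for subtype in templates.subtypes:
        kept = []
        for gene in templates.templates[subtype]:
            if gene in tumor_vs_cl_de.index and abs(tumor_vs_cl_de.at[gene, "lfc"]) > lfc_cutoff:
                rows.append((gene, subtype, "dropped_tumor_cl_de"))
                continue
            if gene not in cell_x.index:
                rows.append((gene, subtype, "dropped_low_expression"))
                continue
            n_high = int((cell_x.loc[gene] >= medians).sum())
            if n_high < min_cell_lines:
                rows.append((gene, subtype, "dropped_low_expression"))
                continue
            kept.append(gene)
            rows.append((gene, subtype, "kept"))
        if not kept:
            raise ValueError(
                f"cell-line relevance filtering emptied the template for {subtype!r}"
            )
        filtered[subtype] = sorted(kept)
    return SubtypeTemplateSet(
        templates=filtered,
        provenance=pd.DataFrame(rows, columns=["gene", "subtype", "status"]),
        n_resample=templates.n_resample,
        seed=templates.seed,
        source_split=templates.source_split,
    )


def _standardize_genes(x: pd.DataFrame) -> pd.DataFrame:
    """Row (gene) z-scores across the cohort being classified."""
    if x.shape[1] < 2:
        raise ValueError(
            "cannot z-score a single-sample cohort; classify it together with "
            "a reference cohort instead"
        )
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1).replace(0.0, 1.0)
    return x.sub(mu, axis=0).div(sd, axis=0)


def ntp_classify(
    x: pd.DataFrame,
    templates: SubtypeTemplateSet,
    n_resample: int | None = None,
    seed: int | None = None,
    fdr_cutoff: float = 0.05,
    min_template_genes: int = 5,
) -> pd.DataFrame:
    """Nearest-template calls with resampling significance.

    Expression is gene-standardized across the classified cohort; each
    subtype's template is the indicator vector of its markers over the
    template-gene union; the call is the smallest cosine distance (ties
    broken by subtype name). The nominal p is the +1-smoothed fraction of
    size-matched random gene sets (drawn from all measured genes) whose
    template distance is at most the observed one; BH-FDR is taken across
    samples and a call is "assigned" iff FDR <= cutoff.
    """
    n_resample = templates.n_resample if n_resample is None else n_resample
    seed = templates.seed if seed is None else seed
    subtypes = templates.subtypes
    present = {
        s: [g for g in templates.templates[s] if g in x.index] for s in subtypes
    }
    too_small = sorted(s for s in subtypes if len(present[s]) < min_template_genes)
    if too_small:
        raise ValueError(
            f"subtypes with fewer than {min_template_genes} template genes "
            f"in the matrix: {too_small}"
        )
    Z = _standardize_genes(x)
    union = [g for s in subtypes for g in present[s]]
    sizes = [len(present[s]) for s in subtypes]
    offsets = np.cumsum([0] + sizes)
    Zu = Z.loc[union].to_numpy(dtype=float)  # (u, n_samples)
    u = len(union)
    norms = np.sqrt((Zu**2).sum(axis=0))
    norms[norms == 0] = 1.0

    # observed cosine distance of every sample to every subtype template
    dist = np.empty((len(subtypes), x.shape[1]))
    for i, s in enumerate(subtypes):
        block = Zu[offsets[i] : offsets[i + 1]]
        cos = block.sum(axis=0) / (norms * np.sqrt(sizes[i]))
        dist[i] = 1.0 - cos
    pred_idx = dist.argmin(axis=0)  # argmin takes the first (name-sorted) on ties
    obs_dist = dist[pred_idx, np.arange(x.shape[1])]

    # null: random gene sets of the same block sizes from all measured genes
    rng = np.random.default_rng(seed)
    Zall = Z.to_numpy(dtype=float)
    n_genes = Zall.shape[0]
    rand_idx = np.empty((n_resample, u), dtype=int)
    for r in range(n_resample):
        rand_idx[r] = rng.choice(n_genes, size=u, replace=False)
    pvals = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        zj = Zall[:, j]
        picks = zj[rand_idx]  # (n_resample, u)
        i = pred_idx[j]
        block_sum = picks[:, offsets[i] : offsets[i + 1]].sum(axis=1)
        rnorm = np.sqrt((picks**2).sum(axis=1))
        rnorm[rnorm == 0] = 1.0
        rdist = 1.0 - block_sum / (rnorm * np.sqrt(sizes[i]))
        pvals[j] = (1 + (rdist <= obs_dist[j]).sum()) / (1 + n_resample)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    calls = pd.DataFrame(
        {
            "subtype": [subtypes[i] for i in pred_idx],
            "distance": obs_dist,
            "p": pvals,
            "fdr": fdr,
            "assigned": fdr <= fdr_cutoff,
        },
        index=x.columns.rename("sample"),
    )
    return calls


def evaluate_accuracy(
    calls: pd.DataFrame, true_labels: pd.Series, gate: float = 0.80
) -> dict:
    """Accuracy over all samples (unassigned counted wrong) and the gate."""
    missing = [s for s in calls.index if s not in true_labels.index]
    if missing:
        raise ValueError(f"samples without a true label: {missing[:5]}")
    truth = true_labels.loc[calls.index]
    correct = (calls["assigned"] & (calls["subtype"] == truth)).sum()
    accuracy = float(correct / len(calls))
    return {
        "accuracy": accuracy,
        "n": int(len(calls)),
        "n_assigned": int(calls["assigned"].sum()),
        "gate_passed": accuracy >= gate,
        "gate": gate,
    }


def subtype_proportion_test(
    tumor_labels: pd.Series, cell_line_calls: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Pearson chi-squared comparison of subtype proportions.

    Unassigned cell lines are excluded; warns when any expected count is
    below 5 (the asymptotic approximation weakens there).
    """
    assigned = cell_line_calls[cell_line_calls["assigned"]]
    if assigned.empty:
        raise ValueError("no assigned cell-line subtype calls")
    table = pd.crosstab(
        pd.concat(
            [
                pd.Series("tumor", index=tumor_labels.index),
                pd.Series("cell_line", index=assigned.index),
            ]
        ),
        pd.concat([tumor_labels, assigned["subtype"]]),
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any() or table.shape[1] < 2:
        raise ValueError("degenerate contingency table (a zero row/column)")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        logger.warning("chi-squared expected counts below 5; p-value is approximate")
    return float(p), table


def subtype_specific_ranks(
    C: CorrelationMatrix, tumor_labels: pd.Series
) -> dict[str, pd.DataFrame]:
    """Cell-line fidelity summaries restricted to each subtype's tumors."""
    out: dict[str, pd.DataFrame] = {}
    for subtype in sorted(tumor_labels.loc[C.rho.columns].unique()):
        cols = [c for c in C.rho.columns if tumor_labels[c] == subtype]
        if not cols:
            logger.warning("subtype %s has no tumors; skipped", subtype)
            continue
        sub = CorrelationMatrix(
            rho=C.rho[cols], genes=C.genes, tumor_type=C.tumor_type
        )
        out[subtype] = summarize_cell_lines(sub)
    return out
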