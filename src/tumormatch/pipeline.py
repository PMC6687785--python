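"""High-level orchestration of the fidelity and subtype analyses.

These functions wire the per-stage modules together for one tumor type:
counts -> upper-quartile scaling -> log2 -> (batch correction) ->
purity filtering/regression -> variable-gene selection -> Spearman
correlation matrix, plus the nearest-template subtype workflow. They are
the entry points the command-line interface and end-to-end tests use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diffexp, fidelity, normalize, purity, subtype
from .config import PipelineConfig

logger = logging.getLogger("tumormatch")

__all__ = ["FidelityResult", "run_fidelity", "SubtypeResult", "run_subtype_workflow"]


@dataclass
class FidelityResult:
    correlation: fidelity.CorrelationMatrix
    summary: pd.DataFrame
    variable_genes: list[str]
    purity_adjusted: bool
    normalized: pd.DataFrame = field(repr=False, default=None)
    purity_filter_report: pd.DataFrame | None = field(repr=False, default=None)


def _split_cohorts(metadata: pd.DataFrame) -> tuple[list[str], list[str]]:
    tumors = list(metadata.index[metadata["cohort"] == "tumor"])
    cells = list(metadata.index[metadata["cohort"] == "cell_line"])
    if not tumors or not cells:
        raise ValueError("metadata must contain both tumor and cell_line samples")
    return tumors, cells


def normalize_counts(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
    batch_correct: bool = True,
) -> pd.DataFrame:
    """Upper-quartile scale, log2-transform and batch-correct the counts.

    Batch correction runs across tumor samples only (platform effects are
    a tumor-cohort artifact here) and only when at least two batches with
    two or more samples each are present.
    """
    config = config or PipelineConfig()
    scaled, _ = normalize.upper_quartile_normalize(counts)
    logged = normalize.log_transform(scaled, pseudocount=config.pseudocount)
    if not batch_correct or "batch" not in metadata.columns:
        return logged
    tumors, _ = _split_cohorts(metadata)
    batches = metadata.loc[tumors, "batch"]
    sizes = batches.value_counts()
    if len(sizes) >= 2 and (sizes >= 2).all():
        corrected = normalize.combat_adjust(logged[tumors], batches)
        logged = logged.copy()
        logged[tumors] = corrected
    else:
        logger.info("batch correction skipped: %d usable batch level(s)", len(sizes))
    return logged


def run_fidelity(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
    adjust_purity: bool = True,
    batch_correct: bool = True,
) -> FidelityResult:
    """Fidelity scoring for one tumor type.

    With ``adjust_purity`` the purity-correlated genes are removed
    (negative-direction filter) and the remaining tumor expression is
    projected to purity 1 before variable-gene selection; cell-line
    columns are never modified by the adjustment.
    """
    config = config or PipelineConfig()
    config.validate()
    tumors, cells = _split_cohorts(metadata)
    tumor_type = str(metadata["tumor_type"].iloc[0]) if "tumor_type" in metadata else ""
    logged = normalize_counts(counts, metadata, config, batch_correct=batch_correct)

    tumor_x = logged[tumors]
    filter_report = None
    if adjust_purity:
        pur = metadata.loc[tumors, "purity"].astype(float)
        filter_report = purity.purity_gene_filter(
            tumor_x,
            pur,
            r_cutoff=config.purity_r_cutoff,
            fdr_cutoff=config.purity_fdr_cutoff,
            mode=config.purity_filter_mode,
        )
        kept = filter_report.index[~filter_report["removed"]]
        tumor_x = purity.regress_out_purity(tumor_x.loc[kept], pur)
        cell_x = logged.loc[kept, cells]
    else:
        cell_x = logged[cells]

    genes = fidelity.select_variable_genes(tumor_x, n=config.n_variable_genes)
    corr = fidelity.spearman_matrix(cell_x, tumor_x, genes, tumor_type=tumor_type)
    summary = fidelity.summarize_cell_lines(corr)
    return FidelityResult(
        correlation=corr,
        summary=summary,
        variable_genes=genes,
        purity_adjusted=adjust_purity,
        normalized=logged,
        purity_filter_report=filter_report,
    )


@dataclass
class SubtypeResult:
    templates: subtype.SubtypeTemplateSet
    filtered_templates: subtype.SubtypeTemplateSet
    test_calls: pd.DataFrame
    test_accuracy: dict
    cell_line_calls: pd.DataFrame | None
    train_ids: list[str]
    test_ids: list[str]


def run_subtype_workflow(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> SubtypeResult:
    """Train/test split, template building + filtering, gated cell-line calls.

    Templates come from one-vs-rest moderated DE on the training tumors;
    the cell-line relevance filter uses a tumor-vs-cell-line DE with
    purity as covariate (cell lines pinned at purity 1). Cell lines are
    classified only when held-out tumor accuracy reaches the gate.
    """
    config = config or PipelineConfig()
    config.validate()
    seed = config.seed if seed is None else seed
    tumors, cells = _split_cohorts(metadata)
    labels = metadata.loc[tumors, "subtype"].astype(str)
    if labels.isna().any() or (labels == "nan").any():
        raise ValueError("every tumor sample needs a subtype label")

    train, test = split_train_test_ids(tumors, labels, config.train_frac, seed)
    templates = subtype.build_templates(
        counts[train],
        labels,
        lfc_cutoff=config.template_lfc_cutoff,
        fdr_cutoff=config.template_fdr_cutoff,
        n_resample=config.n_resample,
        seed=seed,
    )
    design = diffexp.build_design(metadata)
    tumor_vs_cl = diffexp.run_voom_limma(
        counts,
        design,
        lfc_cutoff=config.de_lfc_cutoff,
        fdr_cutoff=config.de_fdr_cutoff,
        span=config.voom_span,
    )
    logged = normalize_counts(counts, metadata, config, batch_correct=False)
    filtered = subtype.filter_templates_for_cell_lines(
        templates, tumor_vs_cl, logged[cells], lfc_cutoff=config.de_lfc_cutoff
    )
    test_calls = subtype.ntp_classify(
        logged[test], filtered, n_resample=config.n_resample, seed=seed,
        fdr_cutoff=config.ntp_fdr_cutoff,
    )
    accuracy = subtype.evaluate_accuracy(
        test_calls, labels.loc[test], gate=config.accuracy_gate
    )
    cell_calls = None
    if accuracy["gate_passed"]:
        cell_calls = subtype.ntp_classify(
            logged[cells], filtered, n_resample=config.n_resample, seed=seed + 1,
            fdr_cutoff=config.ntp_fdr_cutoff,
        )
    else:
        logger.warning(
            "test accuracy %.2f below gate %.2f; cell lines not classified",
            accuracy["accuracy"], config.accuracy_gate,
        )
    return SubtypeResult(
        templates=templates,
        filtered_templates=filtered,
        test_calls=test_calls,
        test_accuracy=accuracy,
        cell_line_calls=cell_calls,
        train_ids=train,
        test_ids=test,
    )


def split_train_test_ids(tumors, labels, train_frac, seed):
    return subtype.split_train_test(tumors, labels, train_frac=train_frac, seed=seed)
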