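"""Tumor-purity handling: combining estimates, filtering purity-correlated
genes, and projecting tumor expression to a pure-tumor reference.

Bulk tumor expression mixes cancer cells with immune/stromal infiltrate;
purity (the cancer-cell fraction) therefore confounds any comparison with
pure cell-line cultures. Two complementary corrections are provided:
dropping genes whose expression tracks contamination (strong *negative*
correlation with purity), and per-gene linear regression that re-expresses
every tumor at purity 1, which is the implicit purity of a cell line.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("tumormatch")

__all__ = [
    "average_purity",
    "signature_purity_estimate",
    "purity_gene_filter",
    "regress_out_purity",
]


def average_purity(p1: pd.Series, p2: pd.Series) -> pd.Series:
    """Arithmetic mean of two purity estimates per sample.

    Samples present in only one input keep that single value (with a
    warning); an empty overlap between two non-empty inputs is an error.
    """
    p1 = p1.dropna()
    p2 = p2.dropna()
    if len(p1) and len(p2) and not p1.index.intersection(p2.index).size:
        raise ValueError("purity vectors share no sample IDs")
    merged = pd.concat([p1.rename("a"), p2.rename("b")], axis=1)
    single = merged.index[merged.isna().any(axis=1)]
    if len(single):
        logger.warning(
            "%d samples have only one purity source; using it as-is", len(single)
        )
    out = merged.mean(axis=1, skipna=True).rename("purity")
    out.attrs["source"] = "averaged"
    return out


def signature_purity_estimate(
    x: pd.DataFrame,
    immune_set: list[str],
    stromal_set: list[str] | None = None,
    min_purity: float = 0.2,
    max_purity: float = 1.0,
) -> pd.Series:
    """Purity proxy from an immune(+stromal) contamination signature.

    The per-sample score is the mean gene-wise z-score over the signature
    genes present in ``x`` (log scale); scores are mapped affinely onto
    ``[min_purity, max_purity]`` with the *highest*-scoring (most
    contaminated) sample at ``min_purity``. This is a lightweight
    signature score for synthetic cohorts, not a calibrated deconvolution.
    """
    stromal_set = stromal_set or []
    genes = [g for g in set(immune_set) | set(stromal_set) if g in x.index]
    if len(genes) < 5:
        raise ValueError(
            f"only {len(genes)} signature genes present in the matrix (need >=5)"
        )
    sub = x.loc[sorted(genes)]
    sd = sub.std(axis=1, ddof=1)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd.replace(0.0, np.nan), axis=0)
    z = z.fillna(0.0)  # constant genes carry no contamination information
    score = z.mean(axis=0)
    lo, hi = score.min(), score.max()
    if hi == lo:
        purity = pd.Series(
            (min_purity + max_purity) / 2.0, index=x.columns, name="purity"
        )
    else:
        purity = min_purity + (hi - score) / (hi - lo) * (max_purity - min_purity)
        purity = purity.rename("purity")
    purity.attrs["source"] = "signature"
    return purity


def purity_gene_filter(
    tumor_x: pd.DataFrame,
    purity: pd.Series,
    r_cutoff: float = -0.4,
    fdr_cutoff: float = 0.01,
    mode: str = "negative",
) -> pd.DataFrame:
    """Flag genes whose expression correlates with purity for removal.

    Pearson correlation of log-expression with purity across tumors, BH
    adjustment across all genes. Under the default ``negative`` mode a
    gene is removed iff ``R <= r_cutoff`` (the contamination direction)
    and adjusted p < cutoff; ``two_sided`` removes on ``|R| >= |r_cutoff|``.
    Returns a frame (gene, R, p, adj_p, removed).
    """
    purity = purity.dropna()
    common = [s for s in tumor_x.columns if s in purity.index]
    if len(common) < 10:
        raise ValueError(f"need >=10 tumors with purity, got {len(common)}")
    p = purity.loc[common].to_numpy(dtype=float)
    if np.ptp(p) == 0:
        raise ValueError("purity has zero variance")
    if mode not in ("negative", "two_sided"):
        raise ValueError(f"unknown purity_filter_mode {mode!r}")

    X = tumor_x[common].to_numpy(dtype=float)
    n = len(common)
    pc = p - p.mean()
    xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (pc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc @ pc / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    # two-sided p from the exact t transform of Pearson r
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    pval = 2 * stats.t.sf(np.abs(t), df=n - 2)
    adj = multipletests(pval, method="fdr_bh")[1]
    if mode == "negative":
        removed = (r <= r_cutoff) & (adj < fdr_cutoff)
    else:
        removed = (np.abs(r) >= abs(r_cutoff)) & (adj < fdr_cutoff)
    logger.info(
        "purity filter (%s mode, R cutoff %.2f): removing %d / %d genes",
        mode, r_cutoff, int(removed.sum()), len(r),
    )
    return pd.DataFrame(
        {"R": r, "p": pval, "adj_p": adj, "removed": removed},
        index=tumor_x.index.rename("gene"),
    )


def regress_out_purity(tumor_x: pd.DataFrame, purity: pd.Series) -> pd.DataFrame:
    """Project tumor log-expression to purity 1 by per-gene OLS.

    For each gene, fit ``expr = a + b * purity`` across tumors; the
    adjusted value is the fit evaluated at purity 1 plus the sample's own
    residual. This removes the linear purity trend (location only — the
    residual variance is untouched) and puts tumors on the same implicit
    purity as cell lines.
    """
    purity = purity.dropna()
    common = [s for s in tumor_x.columns if s in purity.index]
    if len(common) < 3:
        raise ValueError(f"need >=3 tumors with purity, got {len(common)}")
    missing = [s for s in tumor_x.columns if s not in purity.index]
    if missing:
        logger.warning("%d tumor samples lack purity; left unadjusted", len(missing))
    p = purity.loc[common].to_numpy(dtype=float)
    X = tumor_x[common].to_numpy(dtype=float)
    pc = p - p.mean()
    ssp = (pc**2).sum()
    if ssp == 0:
        if np.allclose(p, 1.0):
            # already at the pure-tumor reference: nothing to project
            return tumor_x.copy()
        raise ValueError("purity has zero variance")
    slope = (X - X.mean(axis=1, keepdims=True)) @ pc / ssp
    intercept = X.mean(axis=1) - slope * p.mean()
    fitted = intercept[:, None] + np.outer(slope, p)
    residual = X - fitted
    adjusted = (intercept + slope)[:, None] + residual  # evaluate the line at purity 1
    out = tumor_x.copy()
    out[common] = adjusted
    return out
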