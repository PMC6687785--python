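"""Cell-line fidelity scoring against primary tumors.

A cell line's fidelity to its tumor type is summarized by the Spearman
correlations between its expression profile and every primary tumor of
that type over the most variable genes (interquartile range across the
tumors only). Diagnostics quantify how much tumor purity confounds those
correlations: a quartile contrast (are cell lines more correlated with
high-purity tumors?) and the pooled correlation-vs-purity association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

logger = logging.getLogger("tumormatch")

__all__ = [
    "CorrelationMatrix",
    "select_variable_genes",
    "spearman_matrix",
    "summarize_cell_lines",
    "cross_type_median_matrix",
    "purity_quartile_test",
    "purity_correlation_association",
    "wilcoxon_rank_sum",
    "p_to_stars",
]


@dataclass
class CorrelationMatrix:
    """Cell-line x tumor-sample Spearman rho values for one tumor type."""

    rho: pd.DataFrame
    genes: list[str] = field(default_factory=list)
    tumor_type: str = ""

    @property
    def cell_lines(self) -> pd.Index:
        return self.rho.index

    @property
    def tumors(self) -> pd.Index:
        return self.rho.columns


def select_variable_genes(tumor_x: pd.DataFrame, n: int = 5000) -> list[str]:
    """Top-``n`` genes by interquartile range across tumor samples.

    IQR uses the linear-interpolation (type 7) percentile rule; ties are
    broken lexicographically by gene ID so the list is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    arr = tumor_x.to_numpy(dtype=float)
    q75, q25 = np.percentile(arr, [75, 25], axis=1)
    iqr = pd.Series(q75 - q25, index=tumor_x.index)
    if n > len(iqr):
        logger.warning("requested %d variable genes but only %d exist", n, len(iqr))
        n = len(iqr)
    order = sorted(iqr.index, key=lambda g: (-iqr[g], g))
    return order[:n]


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Average ranks per column."""
    return np.apply_along_axis(stats.rankdata, 0, x)


def spearman_matrix(
    cell_x: pd.DataFrame, tumor_x: pd.DataFrame, genes: list[str],
    tumor_type: str = "",
) -> CorrelationMatrix:
    """Spearman rho between every cell line and every tumor over ``genes``.

    Computed as rank-then-Pearson with average tie ranks. A sample with
    zero variance over the gene list gets missing entries and a warning.
    """
    missing = [g for g in genes if g not in cell_x.index or g not in tumor_x.index]
    if missing:
        raise ValueError(f"genes absent from one of the matrices: {missing[:5]}...")
    C = _rank_columns(cell_x.loc[genes].to_numpy(dtype=float))
    T = _rank_columns(tumor_x.loc[genes].to_numpy(dtype=float))
    Cc = C - C.mean(axis=0, keepdims=True)
    Tc = T - T.mean(axis=0, keepdims=True)
    cn = np.sqrt((Cc**2).sum(axis=0))
    tn = np.sqrt((Tc**2).sum(axis=0))
    degenerate_c = cn == 0
    degenerate_t = tn == 0
    if degenerate_c.any() or degenerate_t.any():
        bad = list(cell_x.columns[degenerate_c]) + list(tumor_x.columns[degenerate_t])
        logger.warning("samples with zero variance over the gene list: %s", bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Cc.T @ Tc) / np.outer(cn, tn)
    rho[degenerate_c, :] = np.nan
    rho[:, degenerate_t] = np.nan
    frame = pd.DataFrame(rho, index=cell_x.columns, columns=tumor_x.columns)
    return CorrelationMatrix(rho=frame, genes=list(genes), tumor_type=tumor_type)


def summarize_cell_lines(C: CorrelationMatrix) -> pd.DataFrame:
    """Per-cell-line median rho, SD of rho, and dense rank by median."""
    if C.rho.empty:
        raise ValueError("empty correlation matrix")
    med = C.rho.median(axis=1)
    sd = C.rho.std(axis=1, ddof=1).fillna(0.0)
    rank = med.rank(ascending=False, method="dense").astype(int)
    return pd.DataFrame(
        {"median_rho": med, "sd_rho": sd, "rank": rank},
        index=C.rho.index.rename("cell_line"),
    ).sort_values(["rank", "cell_line"])


def cross_type_median_matrix(
    matrices: dict[tuple[str, str], CorrelationMatrix],
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """Median rho per (cell-line type, tumor type) pair, with display order.

    ``matrices`` maps ``(cell_line_type, tumor_type)`` to the
    corresponding correlation matrix. Returns the median matrix
    (cell-line types as rows), the row display order from average-linkage
    hierarchical clustering on Euclidean row distances, and a per-tumor-
    type series naming the best-matching cell-line type.
    """
    cl_types = sorted({k[0] for k in matrices})
    tu_types = sorted({k[1] for k in matrices})
    med = pd.DataFrame(np.nan, index=cl_types, columns=tu_types)
    for (ct, tt), cm in matrices.items():
        med.loc[ct, tt] = float(np.nanmedian(cm.rho.to_numpy()))
    if med.isna().any().any():
        raise ValueError("median matrix has missing (cell type, tumor type) pairs")
    if len(cl_types) > 1:
        Z = average(pdist(med.to_numpy(), metric="euclidean"))
        order = [cl_types[i] for i in leaves_list(Z)]
    else:
        order = list(cl_types)
    best_match = med.idxmax(axis=0).rename("best_cell_line_type")
    return med, order, best_match


def _quartile_groups(purity: pd.Series) -> tuple[pd.Index, pd.Index]:
    """Top- and bottom-quartile samples; boundary values go to the middle."""
    q25, q75 = np.percentile(purity.to_numpy(dtype=float), [25, 75])
    top = purity.index[purity > q75]
    bottom = purity.index[purity < q25]
    return top, bottom


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, alternative: str = "greater",
    exact_threshold: int = 20,
) -> float:
    """Two-sample rank-sum p: exact enumeration for small tie-free inputs,
    tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    small = len(x) <= exact_threshold and len(y) <= exact_threshold
    method = "exact" if (no_ties and small) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def p_to_stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def purity_quartile_test(C: CorrelationMatrix, purity: pd.Series) -> dict:
    """One-sided rank-sum test: rho vs top-purity-quartile tumors > rho vs
    bottom-quartile tumors, pooling all cell lines."""
    purity = purity.dropna()
    common = C.rho.columns.intersection(purity.index)
    if len(common) < 4:
        raise ValueError("need >=4 tumors with purity for quartile groups")
    if np.ptp(purity.loc[common].to_numpy()) == 0:
        raise ValueError("purity has zero variance")
    top, bottom = _quartile_groups(purity.loc[common])
    top_rho = C.rho[top].to_numpy().ravel()
    bot_rho = C.rho[bottom].to_numpy().ravel()
    top_rho = top_rho[~np.isnan(top_rho)]
    bot_rho = bot_rho[~np.isnan(bot_rho)]
    p = wilcoxon_rank_sum(top_rho, bot_rho, alternative="greater")
    return {
        "p": p,
        "stars": p_to_stars(p),
        "n_top": int(len(top)),
        "n_bottom": int(len(bottom)),
        "median_top": float(np.median(top_rho)),
        "median_bottom": float(np.median(bot_rho)),
    }


def purity_correlation_association(
    C: CorrelationMatrix, purity: pd.Series
) -> tuple[float, float]:
    """Pearson R (with p) between every (cell line, tumor) rho and that
    tumor's purity, pooled over all pairs."""
    purity = purity.dropna()
    common = C.rho.columns.intersection(purity.index)
    if len(common) < 3:
        raise ValueError("need >=3 tumors with purity")
    p = purity.loc[common].to_numpy(dtype=float)
    if np.ptp(p) == 0:
        raise ValueError("purity has zero variance")
    rho = C.rho[common].to_numpy()
    purity_rep = np.broadcast_to(p, rho.shape)
    mask = ~np.isnan(rho)
    r, pval = stats.pearsonr(rho[mask], purity_rep[mask])
    return float(r), float(pval)
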