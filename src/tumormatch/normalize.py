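"""Count normalization and batch correction.

The preprocessing chain for cross-cohort comparison is upper-quartile
scaling of raw counts, a log2 transform, and (where two sequencing
platforms are mixed) a parametric empirical-Bayes location/scale batch
adjustment of the kind usually called ComBat. Quantile normalization is
used inside the differential-expression precision-weighting step.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("tumormatch")

__all__ = [
    "upper_quartile_normalize",
    "log_transform",
    "quantile_normalize",
    "combat_adjust",
]


def upper_quartile_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample so its 75th percentile of nonzero counts is common.

    The per-sample upper quartile is the linear-interpolation (type 7)
    75th percentile of that sample's *nonzero* counts; the common target
    is the geometric mean of the per-sample quartiles, which makes the
    operation scale-free and idempotent. Returns the scaled matrix and
    the per-sample scaling factors (column / factor = output).
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    uq = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        nonzero = arr[:, j][arr[:, j] > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {counts.columns[j]!r} has all-zero counts")
        uq[j] = np.percentile(nonzero, 75)
    reference = float(np.exp(np.mean(np.log(uq))))
    factors = pd.Series(uq / reference, index=counts.columns, name="uq_factor")
    scaled = counts / factors
    return scaled, factors


def log_transform(x: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount); input must be non-negative."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (x.to_numpy() < 0).any():
        raise ValueError("log_transform requires non-negative input")
    return np.log2(x + pseudocount)


def quantile_normalize(x: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution.

    The reference distribution is the across-sample mean of column-sorted
    values; tied values within a column receive the mean of the reference
    values their ranks span (the ``ties="average"`` convention).
    """
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    arr = x.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        # average rank r maps to the mean of reference order statistics the
        # tie group spans; for untied values this is reference[rank-1]
        ranks = rankdata(arr[:, j], method="average")
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
        # exact tie groups wider than 2 need the full span mean
        col = arr[:, j]
        if np.unique(col).size < col.size:
            order = np.argsort(col, kind="mergesort")
            sorted_col = col[order]
            start = 0
            for end in range(1, col.size + 1):
                if end == col.size or sorted_col[end] != sorted_col[start]:
                    if end - start > 1:
                        out[order[start:end], j] = reference[start:end].mean()
                    start = end
    return pd.DataFrame(out, index=x.index, columns=x.columns)


def combat_adjust(
    x: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Parametric empirical-Bayes batch adjustment (location and scale).

    Gene-wise: the data are standardized against the batch-size-weighted
    grand mean (plus any covariate effects) and pooled variance; per-batch
    location (gamma) and scale (delta^2) estimates are shrunk toward
    normal / inverse-gamma priors whose hyperparameters are estimated by
    method of moments across genes; the data are then adjusted and
    de-standardized. Genes with zero pooled variance pass through
    untouched, and the output is re-centered so each gene's grand mean is
    preserved exactly.
    """
    batch = batch.reindex(x.columns)
    if batch.isna().any():
        missing = list(x.columns[batch.isna()])
        raise ValueError(f"samples without batch label: {missing}")
    levels = sorted(batch.unique())
    if len(levels) == 1:
        logger.warning("single batch %r: combat_adjust is the identity", levels[0])
        return x.copy()
    sizes = batch.value_counts()
    small = sorted(sizes.index[sizes < 2])
    if small:
        raise ValueError(f"batches with fewer than 2 samples: {small}")

    Y = x.to_numpy(dtype=float)
    n_genes, n_samples = Y.shape
    masks = {b: (batch == b).to_numpy() for b in levels}
    n_b = {b: int(masks[b].sum()) for b in levels}

    # design for the standardization fit: batch indicators (+ covariates)
    design_cols = [masks[b].astype(float) for b in levels]
    if covariates is not None:
        cov = covariates.reindex(x.columns).to_numpy(dtype=float)
        design_cols.extend(cov[:, j] for j in range(cov.shape[1]))
    X = np.column_stack(design_cols)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p, genes)
    grand = np.zeros(n_genes)
    for i, b in enumerate(levels):
        grand += (n_b[b] / n_samples) * beta[i]
    stand_mean = np.tile(grand[:, None], (1, n_samples))
    if covariates is not None:
        stand_mean += (X[:, len(levels):] @ beta[len(levels):]).T
    resid = Y - (X @ beta).T
    var_pooled = (resid**2).mean(axis=1)

    keep = var_pooled > 0
    Z = np.zeros_like(Y)
    Z[keep] = (Y[keep] - stand_mean[keep]) / np.sqrt(var_pooled[keep])[:, None]

    adjusted = Y.copy()
    Zadj = np.empty_like(Z)
    for b in levels:
        m = masks[b]
        gamma_hat = Z[keep][:, m].mean(axis=1)
        # ddof=0 matches the pooled-variance denominator, so equal batches
        # give delta_hat == 1 exactly and the adjustment is the identity
        delta_hat = Z[keep][:, m].var(axis=1, ddof=0)
        gamma_bar = gamma_hat.mean()
        tau_sq = gamma_hat.var(ddof=1)
        # inverse-gamma prior moments for the scale factors
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        lam = (d_mean**2 + 2 * d_var) / d_var if d_var > 0 else np.inf
        theta = (d_mean**3 + d_mean * d_var) / d_var if d_var > 0 else d_mean
        gamma_star, delta_star = _eb_iterate(
            Z[keep][:, m], gamma_hat, delta_hat, gamma_bar, tau_sq, lam, theta
        )
        Zadj[np.ix_(keep, m)] = (Z[keep][:, m] - gamma_star[:, None]) / np.sqrt(
            delta_star
        )[:, None]
    adjusted[keep] = Zadj[keep] * np.sqrt(var_pooled[keep])[:, None] + stand_mean[keep]
    # location-only recentering: preserve each gene's grand mean exactly
    adjusted[keep] += (Y[keep].mean(axis=1) - adjusted[keep].mean(axis=1))[:, None]
    return pd.DataFrame(adjusted, index=x.index, columns=x.columns)


def _eb_iterate(Zb, gamma_hat, delta_hat, gamma_bar, tau_sq, lam, theta,
                tol: float = 1e-6, max_iter: int = 200):
    """Iterative solution of the coupled EB posterior equations."""
    n = Zb.shape[1]
    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    if tau_sq <= 0 or not np.isfinite(lam):
        # degenerate priors (e.g. near-identical genes): no shrinkage
        return gamma_hat, np.maximum(delta_hat, 1e-12)
    for _ in range(max_iter):
        gamma_new = (n * tau_sq * gamma_hat + delta * gamma_bar) / (n * tau_sq + delta)
        ssq = ((Zb - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (theta + 0.5 * ssq) / (n / 2 + lam - 1)
        change = max(
            np.abs(gamma_new - gamma).max(initial=0.0),
            np.abs(delta_new - delta).max(initial=0.0),
        )
        gamma, delta = gamma_new, delta_new
        if change < tol:
            break
    return gamma, np.maximum(delta, 1e-12)
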