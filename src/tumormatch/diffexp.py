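"""Count-based differential expression with precision weights and
empirical-Bayes moderated statistics.

The procedure mirrors the standard limma/voom analysis for RNA-seq:
log-CPM transformation, quantile normalization, a locally weighted fit of
sqrt-residual-SD against mean log-count giving per-observation inverse-
variance weights, gene-wise weighted least squares on an arbitrary design
(here: intercept + tumor/cell-line indicator + purity covariate, with
cell lines pinned at purity 1), and moderation of the residual variances
toward a scaled inverse chi-square prior whose hyperparameters (d0, s0^2)
are estimated by matching moments of log s^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .normalize import quantile_normalize

logger = logging.getLogger("tumormatch")

__all__ = [
    "build_design",
    "voom_weights",
    "fit_weighted_lm",
    "ebayes_moderate",
    "call_de",
    "consistent_genes",
    "run_voom_limma",
]

#: floor on the predicted sqrt-residual-SD so weights stay finite
TREND_FLOOR = 1e-4


@dataclass
class LinearFits:
    """Per-gene WLS results for one shared design."""

    coefficients: pd.DataFrame  # genes x design columns
    s2: pd.Series  # residual variance
    df_residual: float
    unscaled_var: pd.Series  # (X'WX)^-1 diagonal for the contrast column
    contrast: str


def build_design(
    metadata: pd.DataFrame,
    group_col: str = "cohort",
    tumor_level: str = "tumor",
    purity_col: str | None = "purity",
) -> pd.DataFrame:
    """Intercept + tumor indicator (+ purity, cell lines fixed at 1).

    The group coefficient is the tumor-vs-cell-line log2 fold change, so
    positive LFC means up in tumors.
    """
    design = pd.DataFrame(index=metadata.index)
    design["intercept"] = 1.0
    design["group"] = (metadata[group_col] == tumor_level).astype(float)
    if purity_col is not None and purity_col in metadata.columns:
        purity = metadata[purity_col].astype(float).copy()
        purity[metadata[group_col] != tumor_level] = 1.0
        if purity.isna().any():
            missing = list(metadata.index[purity.isna()])
            raise ValueError(f"tumor samples without purity: {missing[:5]}")
        design["purity"] = purity
    return design


def logcpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    return np.log2((counts + 0.5).div(lib + 1.0, axis=1) * 1e6)


def voom_weights(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    span: float = 0.5,
    quantile_norm: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-CPM matrix plus inverse-variance precision weights.

    The mean-variance trend is fit by lowess of sqrt residual SD on
    average log2 count, then evaluated at each observation's fitted
    log-count; weights are 1 / trend^4. With ``quantile_norm`` the
    log-CPM matrix is quantile-normalized before the residual fit.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    X = design.to_numpy(dtype=float)
    n, p = X.shape[0], X.shape[1]
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} samples for a {p}-column design")
    y = logcpm(counts)
    if quantile_norm and y.shape[1] >= 2:
        y = quantile_normalize(y)
    Y = y.to_numpy(dtype=float)

    # gene-wise unweighted OLS residual SD
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    df_resid = n - p
    s2 = ((Y - fitted) ** 2).sum(axis=1) / df_resid
    sqrt_sd = np.sqrt(np.sqrt(s2))

    # mean log2 count per gene and per observation (on the count scale)
    log2_lib_gm = np.mean(np.log2(lib + 1.0))
    sx = Y.mean(axis=1) + log2_lib_gm - np.log2(1e6)
    trend = lowess(sqrt_sd, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], TREND_FLOOR)
    # per-observation fitted log2 count from the gene's fitted logCPM
    obs_logcount = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(obs_logcount, tx, ty)  # flat extrapolation at the ends
    weights = 1.0 / pred**4
    return y, pd.DataFrame(weights, index=counts.index, columns=counts.columns)


def fit_weighted_lm(
    y: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: pd.DataFrame,
    contrast: str = "group",
) -> LinearFits:
    """Gene-wise weighted least squares on a shared design.

    Weights are rescaled per gene to unit mean so the fit (and s^2) is
    invariant to a common rescaling of the weights. Raises on a rank-
    deficient design, naming the collinear columns.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X.T)
        pairs = [
            (design.columns[i], design.columns[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 0.999999
        ]
        raise ValueError(f"design is rank deficient (rank {rank} < {p}); "
                         f"suspect columns: {pairs or list(design.columns)}")
    if contrast not in design.columns:
        raise ValueError(f"contrast column {contrast!r} not in design")
    Y = y.to_numpy(dtype=float)
    G = Y.shape[0]
    if weights is None:
        W = np.ones_like(Y)
    else:
        W = weights.to_numpy(dtype=float)
        W = W / W.mean(axis=1, keepdims=True)

    XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
    XtWy = np.einsum("ni,gn,gn->gi", X, W, Y)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]  # (G, p)
    resid = Y - beta @ X.T
    df_resid = n - p
    s2 = np.einsum("gn,gn->g", W, resid**2) / df_resid
    inv = np.linalg.inv(XtWX)
    c = list(design.columns).index(contrast)
    unscaled = inv[:, c, c]
    return LinearFits(
        coefficients=pd.DataFrame(beta, index=y.index, columns=design.columns),
        s2=pd.Series(s2, index=y.index, name="s2"),
        df_residual=float(df_resid),
        unscaled_var=pd.Series(unscaled, index=y.index, name="unscaled_var"),
        contrast=contrast,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a log-convex scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments (d0, s0^2) for the scaled inverse chi-square
    variance prior, from the empirical distribution of log s^2."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 10:
        raise ValueError("need >=10 genes with positive variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = z.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        # no excess spread in log s^2 beyond sampling: infinite prior df,
        # the pooled (arithmetic mean) variance is the common variance
        return np.inf, float(s2[ok].mean())
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def ebayes_moderate(
    fits: LinearFits,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Moderated t-table for the contrast coefficient.

    Posterior variance ``s~^2 = (d0*s0^2 + d*s^2) / (d0 + d)``; the
    moderated t uses ``d0 + d`` degrees of freedom. ``d0``/``s0_sq`` may
    be injected (e.g. for validation); by default they are estimated by
    method of moments. When all variances coincide the prior df is
    infinite and the pooled variance is used with a normal reference.
    """
    if len(fits.s2) < 10:
        raise ValueError("moderation needs >=10 genes")
    d = fits.df_residual
    if d0 is None or s0_sq is None:
        d0_est, s0_est = estimate_prior(fits.s2.to_numpy(), d)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
    s2 = fits.s2.to_numpy(dtype=float)
    if np.isinf(d0):
        logger.info("infinite prior df: using pooled variance s0^2=%.4g", s0_sq)
        post_var = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        post_var = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    lfc = fits.coefficients[fits.contrast].to_numpy(dtype=float)
    se = np.sqrt(post_var * fits.unscaled_var.to_numpy(dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df=df_total)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "lfc": lfc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "de": False,
            "direction": np.where(lfc >= 0, "up_in_tumor", "up_in_cell_line"),
        },
        index=fits.s2.index.rename("gene"),
    )
    table.attrs["d0"] = float(d0)
    table.attrs["s0_sq"] = float(s0_sq)
    return table


def call_de(
    table: pd.DataFrame, lfc_cutoff: float = 2.0, fdr_cutoff: float = 0.01
) -> pd.DataFrame:
    """Set DE flags: FDR < cutoff AND |LFC| > cutoff."""
    out = table.copy()
    out["de"] = (out["fdr"] < fdr_cutoff) & (out["lfc"].abs() > lfc_cutoff)
    n_up = int((out["de"] & (out["direction"] == "up_in_tumor")).sum())
    n_down = int((out["de"] & (out["direction"] == "up_in_cell_line")).sum())
    out.attrs.update(table.attrs)
    out.attrs["n_up_in_tumor"] = n_up
    out.attrs["n_up_in_cell_line"] = n_down
    return out


def consistent_genes(
    tables: dict[str, pd.DataFrame],
    min_types: int,
    direction: str = "up_in_tumor",
) -> list[str]:
    """Genes DE in the given direction in at least ``min_types`` tables."""
    if len(tables) < min_types:
        raise ValueError(
            f"min_types={min_types} exceeds the {len(tables)} tables provided"
        )
    counts: dict[str, int] = {}
    for table in tables.values():
        hits = table.index[table["de"] & (table["direction"] == direction)]
        for g in hits:
            counts[g] = counts.get(g, 0) + 1
    return sorted(g for g, c in counts.items() if c >= min_types)


def run_voom_limma(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: str = "group",
    lfc_cutoff: float = 2.0,
    fdr_cutoff: float = 0.01,
    span: float = 0.5,
) -> pd.DataFrame:
    """Full chain: voom weights -> WLS -> moderation -> DE calls."""
    y, w = voom_weights(counts, design, span=span)
    fits = fit_weighted_lm(y, w, design, contrast=contrast)
    table = ebayes_moderate(fits)
    return call_de(table, lfc_cutoff=lfc_cutoff, fdr_cutoff=fdr_cutoff)
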