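"""Classic (unweighted) preranked gene-set enrichment.

Genes are ranked by a score (log2 fold change here); walking down the
list, the running sum gains ``1/|S|`` at each gene-set member (hit) and
loses ``1/(N-|S|)`` at each non-member. The enrichment score (ES) is the
maximum-magnitude deviation of that running sum; it lies in [-1, 1] and
is positive when the set concentrates at the top of the list. A null ES
distribution from random gene sets of the same size yields normalized
scores (NES), nominal p-values, and ratio-of-tails FDR q-values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("tumormatch")

__all__ = [
    "rank_genes",
    "enrichment_score",
    "preranked_gsea",
    "significant_sets",
]


def rank_genes(scores: pd.Series) -> list[str]:
    """Descending order by score, ties broken by gene ID (deterministic)."""
    if scores.index.duplicated().any():
        dup = scores.index[scores.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate genes in ranking: {dup[:5]}")
    return sorted(scores.index, key=lambda g: (-scores[g], g))


def enrichment_score(
    ranked: list[str], gene_set: set[str] | list[str]
) -> tuple[float, np.ndarray, list[str]]:
    """ES, the full running sum, and the leading-edge genes.

    Leading edge: for positive ES the set members at or before the running
    sum's maximum; for negative ES the members after the minimum.
    """
    gene_set = set(gene_set)
    N = len(ranked)
    hits = np.fromiter((g in gene_set for g in ranked), dtype=bool, count=N)
    k = int(hits.sum())
    if k == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if k == N:
        raise ValueError("gene set covers the whole ranked list")
    inc = np.where(hits, 1.0 / k, -1.0 / (N - k))
    running = np.cumsum(inc)
    # closed-form extrema at the hit positions; identical arithmetic to the
    # vectorized permutation path so tie-breaks agree bitwise
    pos = np.flatnonzero(hits) + 1
    j = np.arange(1, k + 1)
    at_hit = j / k - (pos - j) / (N - k)
    before_hit = (j - 1) / k - (pos - j) / (N - k)
    pos_max = at_hit.max()
    neg_min = min(before_hit.min(), 0.0)
    if pos_max >= -neg_min:
        es = float(pos_max)
        i_max = int(pos[int(np.argmax(at_hit))]) - 1
        leading = [g for g, h in zip(ranked[: i_max + 1], hits[: i_max + 1]) if h]
    else:
        es = float(neg_min)
        i_min = int(pos[int(np.argmin(before_hit))]) - 2
        leading = [g for g, h in zip(ranked[i_min + 1 :], hits[i_min + 1 :]) if h]
    return es, running, leading


def _es_from_positions(pos_sorted: np.ndarray, N: int) -> np.ndarray:
    """Vectorized ES for many sets given sorted hit positions (1-based).

    ``pos_sorted`` has shape (n_sets, k). The running sum's candidate
    extremes occur exactly at each hit (for the maximum) and just before
    each hit (for the minimum).
    """
    n_sets, k = pos_sorted.shape
    j = np.arange(1, k + 1)
    miss_inc = 1.0 / (N - k)
    at_hit = j / k - (pos_sorted - j) * miss_inc
    before_hit = (j - 1) / k - (pos_sorted - j) * miss_inc
    pos_max = at_hit.max(axis=1)
    neg_min = np.minimum(before_hit.min(axis=1), 0.0)
    # the running sum also ends at 0, so the max candidate is >= final sum
    return np.where(pos_max >= -neg_min, pos_max, neg_min)


def _null_es(N: int, k: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null ES from ``n_perm`` uniformly random k-subsets of N positions."""
    u = rng.random((n_perm, N))
    pos = np.argpartition(u, k, axis=1)[:, :k]
    pos.sort(axis=1)
    return _es_from_positions(pos + 1, N)


def preranked_gsea(
    scores: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked enrichment over a gene-set collection.

    Per set: ES on the observed ranking; a size-matched random-set null
    (cached per intersection size, all sets of one size share it);
    NES = ES / mean(|null ES| of matching sign); nominal p = same-sign
    tail fraction; FDR q by the ratio-of-tails rule on the pooled
    sign-matched NES null, made monotone. Deterministic given ``seed``.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; q-values will be unstable", n_perm)
    ranked = rank_genes(scores)
    N = len(ranked)
    universe = set(ranked)
    rng = np.random.default_rng(seed)

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    null_nes_pool: list[np.ndarray] = []
    for name in sets:
        overlap = [g for g in sets[name] if g in universe]
        k = len(overlap)
        if k == 0:
            logger.warning("set %s has no overlap with the ranked list; skipped", name)
            continue
        if not (min_size <= k <= max_size):
            logger.info("set %s outside size bounds (overlap %d); skipped", name, k)
            continue
        es, _, leading = enrichment_score(ranked, overlap)
        if k not in null_cache:
            null_cache[k] = _null_es(N, k, n_perm, rng)
        null = null_cache[k]
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        if es >= 0:
            denom = pos_null.mean() if pos_null.size else np.nan
            same = pos_null
            p = (same >= es).sum() / same.size if same.size else 1.0
        else:
            denom = -neg_null.mean() if neg_null.size else np.nan
            same = neg_null
            p = (same <= es).sum() / same.size if same.size else 1.0
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        # sign-matched normalized null, pooled across sets for the FDR
        null_nes = np.concatenate([
            pos_null / pos_null.mean() if pos_null.size else np.empty(0),
            neg_null / (-neg_null.mean()) if neg_null.size else np.empty(0),
        ])
        null_nes_pool.append(null_nes)
        rows.append(
            {
                "set": name,
                "size": k,
                "es": es,
                "nes": nes,
                "p": float(p),
                "leading_edge_size": len(leading),
                "leading_edge": ";".join(leading),
            }
        )
    result = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p", "q", "leading_edge_size", "leading_edge"]
    )
    if not len(result):
        return result
    pooled = np.concatenate(null_nes_pool)
    result["q"] = _ratio_of_tails_q(result["nes"].to_numpy(), pooled)
    return result[["size", "es", "nes", "p", "q", "leading_edge_size", "leading_edge"]]


def _ratio_of_tails_q(nes: np.ndarray, pooled_null: np.ndarray) -> np.ndarray:
    """GSEA-style FDR: (null tail fraction) / (observed tail fraction),
    computed within each sign, capped at 1 and made monotone in |NES|."""
    q = np.ones_like(nes, dtype=float)
    for sign in (1, -1):
        if sign > 0:
            idx = np.where(nes >= 0)[0]
            null_side = pooled_null[pooled_null >= 0]
        else:
            idx = np.where(nes < 0)[0]
            null_side = pooled_null[pooled_null < 0]
        if idx.size == 0:
            continue
        obs_side = nes[idx]
        for i in idx:
            v = nes[i]
            if not np.isfinite(v):
                q[i] = np.nan
                continue
            null_tail = (
                (null_side >= v).mean() if sign > 0 else (null_side <= v).mean()
            ) if null_side.size else 1.0
            obs_tail = (
                (obs_side >= v).mean() if sign > 0 else (obs_side <= v).mean()
            )
            q[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
        # monotone cleanup: a more extreme NES never has a larger q
        order = np.argsort(-np.abs(nes[idx]))
        running = np.inf
        for i in idx[order]:
            if np.isfinite(q[i]):
                running = min(running, q[i])
                q[i] = running
    return q


def significant_sets(results: pd.DataFrame, q_cutoff: float = 0.05) -> pd.DataFrame:
    """Sets with q < cutoff, labeled by enrichment direction.

    Positive NES means the set concentrates at the top of the ranking
    (up in tumors under the pipeline's LFC sign convention).
    """
    if results.empty:
        out = results.copy()
        out["direction"] = pd.Series(dtype=str)
        return out
    out = results[results["q"] < q_cutoff].copy()
    out["direction"] = np.where(out["nes"] >= 0, "tumor", "cell_line")
    return out
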