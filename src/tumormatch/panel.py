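"""Representative cell-line panel construction and comparison.

Two selection rules over per-type fidelity summaries (median Spearman rho
per cell line): a fixed-composition panel that takes the top lines per
tumor type, and a subtype-diverse panel that first takes the best line
within each assigned subtype (most prevalent subtype first) before
filling remaining slots by overall median rho. Panels are compared by a
two-sided rank-sum test on their per-line median correlations. No
minimum-correlation floor is applied for inclusion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tumormatch")

__all__ = [
    "improved_fixed_panel",
    "subtype_diverse_panel",
    "compare_panels",
]

_COLUMNS = ["cell_line", "tumor_type", "median_rho", "subtype", "reason"]


def _top_by_median(summary: pd.DataFrame, count: int) -> list[str]:
    """Cell lines sorted by median rho descending, ID ascending on ties."""
    order = sorted(summary.index, key=lambda c: (-summary.at[c, "median_rho"], c))
    return order[:count]


def improved_fixed_panel(
    summaries: dict[str, pd.DataFrame], composition: dict[str, int]
) -> pd.DataFrame:
    """Top-``count`` cell lines by median rho for each requested type.

    ``summaries`` maps tumor type to a per-cell-line summary frame (as
    produced by :func:`tumormatch.fidelity.summarize_cell_lines`);
    ``composition`` maps tumor type to the number of lines wanted.
    Deterministic: ties broken by cell-line ID.
    """
    rows = []
    for tumor_type in sorted(composition):
        count = composition[tumor_type]
        if tumor_type not in summaries:
            raise ValueError(f"no fidelity summary for tumor type {tumor_type!r}")
        summary = summaries[tumor_type]
        if len(summary) < count:
            raise ValueError(
                f"tumor type {tumor_type!r} has {len(summary)} cell lines, "
                f"{count} requested"
            )
        for cl in _top_by_median(summary, count):
            rows.append((cl, tumor_type, float(summary.at[cl, "median_rho"]), "", "rank_overall"))
    panel = pd.DataFrame(rows, columns=_COLUMNS)
    dup = panel["cell_line"][panel["cell_line"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate cell lines across types: {dup}")
    return panel


def subtype_diverse_panel(
    summaries: dict[str, pd.DataFrame],
    subtype_calls: dict[str, pd.DataFrame] | None,
    k: int = 5,
) -> pd.DataFrame:
    """k lines per tumor type, maximizing subtype representation.

    For types with assigned subtype calls: subtypes are visited in
    decreasing prevalence among the assigned calls (ties by name) and the
    best line of each is taken; remaining slots (or types without calls)
    are filled by overall median rho among the lines not yet chosen.
    """
    subtype_calls = subtype_calls or {}
    rows = []
    for tumor_type in sorted(summaries):
        summary = summaries[tumor_type]
        want = k
        if len(summary) < k:
            logger.warning(
                "tumor type %s has only %d cell lines (k=%d); taking all",
                tumor_type, len(summary), k,
            )
            want = len(summary)
        chosen: list[tuple[str, str, str]] = []  # (cell line, subtype, reason)
        calls = subtype_calls.get(tumor_type)
        if calls is not None:
            assigned = calls[calls["assigned"]]
            assigned = assigned[assigned.index.isin(summary.index)]
            prevalence = assigned["subtype"].value_counts()
            ordered_subtypes = sorted(
                prevalence.index, key=lambda s: (-prevalence[s], s)
            )
            for subtype in ordered_subtypes[:want]:
                members = assigned.index[assigned["subtype"] == subtype]
                sub_summary = summary.loc[members]
                best = _top_by_median(sub_summary, 1)[0]
                chosen.append((best, subtype, "rank_within_subtype"))
        taken = {c for c, _, _ in chosen}
        remaining = summary.drop(index=[c for c in taken])
        for cl in _top_by_median(remaining, want - len(chosen)):
            subtype = ""
            if calls is not None and cl in calls.index and calls.at[cl, "assigned"]:
                subtype = calls.at[cl, "subtype"]
            chosen.append((cl, subtype, "rank_overall"))
        for cl, subtype, reason in chosen:
            rows.append(
                (cl, tumor_type, float(summary.at[cl, "median_rho"]), subtype, reason)
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def compare_panels(panel_a: pd.DataFrame, panel_b: pd.DataFrame,
                   alternative: str = "two-sided") -> float:
    """Rank-sum test on the two panels' per-cell-line median rho values."""
    if panel_a.empty or panel_b.empty:
        raise ValueError("both panels must be non-empty")
    a = panel_a["median_rho"].to_numpy(dtype=float)
    b = panel_b["median_rho"].to_numpy(dtype=float)
    if len(a) == len(b) and sorted(panel_a["cell_line"]) == sorted(panel_b["cell_line"]):
        logger.warning("comparing a panel with itself: p = 1 trivially")
    pooled = np.concatenate([a, b])
    exact = np.unique(pooled).size == pooled.size and max(len(a), len(b)) <= 20
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)
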