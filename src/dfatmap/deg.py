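"""Wilcoxon rank-sum marker detection between cell groups.

Marker criteria follow the FindMarkers-style convention: two-sided Wilcoxon
rank-sum p-value, log2 fold change on the back-transformed normalized scale,
and an expression-fraction pre-filter.  Defaults: log2FC > 0.25, adjusted
p < 0.05 (Bonferroni), gene expressed in > 25% of cells of either group.

The rank-sum p-value is exact (tie-aware subset-sum enumeration via dynamic
programming) when both groups have <= 25 observations, and a normal
approximation with tie correction and continuity correction otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix

__all__ = [
    "DEGParams",
    "rank_sum_test",
    "log2_fold_change",
    "adjust_pvalues",
    "find_markers",
]

_EXACT_MAX_PER_GROUP = 25


@dataclass(frozen=True)
class DEGParams:
    """Marker-calling criteria and options."""

    logfc_min: float = 0.25
    padj_max: float = 0.05
    min_pct: float = 0.25
    pseudocount: float = 1e-9
    adjust_method: str = "bonferroni"  # or "bh"

    def __post_init__(self) -> None:
        if not 0 < self.padj_max < 1:
            raise ValueError("padj_max must be in (0, 1)")
        if not 0 <= self.min_pct <= 1:
            raise ValueError("min_pct must be in [0, 1]")
        if self.adjust_method not in ("bonferroni", "bh"):
            raise ValueError("adjust_method must be 'bonferroni' or 'bh'")


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by counting all C(n, n1) group assignments.

    Ties are handled by midranks; doubling the midranks makes every rank an
    integer so the null distribution of the rank sum is a subset-sum count,
    computed by dynamic programming.  Counts stay below 2^53 for n <= 50, so
    float64 arithmetic is exact.
    """
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    r2 = np.round(2 * rankdata(pooled)).astype(int)  # doubled midranks
    w_obs = int(r2[:n1].sum())
    mu2 = n1 * (n + 1)  # doubled null mean of the rank sum
    total = int(r2.sum())

    # dp[j, s] = number of j-subsets of the ranks seen so far with sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        dp[1:, r:] += dp[:-1, : total + 1 - r]

    dev = abs(w_obs - mu2)
    sums = np.arange(total + 1)  # subset sums are doubled rank sums
    extreme = np.abs(sums - mu2) >= dev
    n_extreme = dp[n1, extreme].sum()
    n_total = dp[n1, :].sum()
    return float(min(1.0, n_extreme / n_total))


def _asymptotic_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Normal approximation with midrank tie correction and continuity correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all pooled values identical
        return 1.0
    from scipy.stats import norm

    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2 * norm.sf(z)))


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration (tie-aware) when both groups have <= 25 values, normal
    approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size <= _EXACT_MAX_PER_GROUP and y.size <= _EXACT_MAX_PER_GROUP:
        return _exact_ranksum_p(x, y)
    return _asymptotic_ranksum_p(x, y)


def log2_fold_change(
    nm: NormalizedMatrix,
    gene: str,
    in_cells,
    out_cells,
    pseudocount: float = 1e-9,
) -> float:
    """log2 ratio of group means on the back-transformed (expm1) scale."""
    gi = nm.genes.get_loc(gene)
    row = np.asarray(nm.values[gi, :].todense()).ravel()
    ii = nm.cells.get_indexer(pd.Index(in_cells))
    oi = nm.cells.get_indexer(pd.Index(out_cells))
    if (ii < 0).any() or (oi < 0).any():
        raise KeyError("unknown cell ids in group definitions")
    m_in = np.expm1(row[ii]).mean()
    m_out = np.expm1(row[oi]).mean()
    return float(np.log2((m_in + pseudocount) / (m_out + pseudocount)))


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment, order-preserving with the input.

    ``bonferroni``: min(1, m*p).  ``bh``: Benjamini-Hochberg step-up.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def find_markers(
    nm: NormalizedMatrix,
    labels: pd.Series,
    target_cluster,
    params: DEGParams | None = None,
) -> pd.DataFrame:
    """Markers of ``target_cluster`` versus all other cells.

    Genes are pre-filtered unless expressed (value > 0) in more than
    ``min_pct`` of the in-group or the out-group; the adjustment is computed
    over the tested genes only.  Rows passing ``log2fc > logfc_min`` and
    ``p_adj < padj_max`` are returned sorted by descending log2fc (ties by
    gene id).
    """
    if params is None:
        params = DEGParams()
    labels = labels.reindex(nm.cells)
    if labels.isna().any():
        raise ValueError("labels missing for some cells")
    in_mask = (labels == target_cluster).to_numpy()
    if in_mask.sum() == 0:
        raise KeyError(f"unknown cluster {target_cluster!r}")
    if in_mask.sum() < 3:
        raise ValueError("target cluster must have at least 3 cells")
    out_mask = ~in_mask

    dense = np.asarray(nm.values.todense(), dtype=float)
    n_in, n_out = int(in_mask.sum()), int(out_mask.sum())
    pct_in = (dense[:, in_mask] > 0).mean(axis=1)
    pct_out = (dense[:, out_mask] > 0).mean(axis=1)
    tested = np.maximum(pct_in, pct_out) > params.min_pct

    expm1 = np.expm1(dense)
    m_in = expm1[:, in_mask].mean(axis=1)
    m_out = expm1[:, out_mask].mean(axis=1)
    log2fc = np.log2((m_in + params.pseudocount) / (m_out + params.pseudocount))

    tested_idx = np.flatnonzero(tested)
    pvals = np.array(
        [rank_sum_test(dense[g, in_mask], dense[g, out_mask]) for g in tested_idx]
    )
    padj = adjust_pvalues(pvals, params.adjust_method)

    keep = (log2fc[tested_idx] > params.logfc_min) & (padj < params.padj_max)
    rows = pd.DataFrame(
        {
            "gene": nm.genes[tested_idx[keep]],
            "cluster": target_cluster,
            "log2fc": log2fc[tested_idx[keep]],
            "p": pvals[keep],
            "p_adj": padj[keep],
            "pct_in": pct_in[tested_idx[keep]],
            "pct_out": pct_out[tested_idx[keep]],
        }
    )
    rows = rows.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return rows
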