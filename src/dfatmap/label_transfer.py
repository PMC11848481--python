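"""Cluster-similarity label transfer.

Each reference subpopulation contributes its top-50 markers (by descending
log2 fold change from the reference DEG tables); a query cell's similarity
score for a subpopulation is the mean log-normalized expression of those
markers, and the cell is assigned to the best-scoring subpopulation.
Assignments are aggregated per query subpopulation into a Sankey-style
mapping table of counts and fractions.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix

__all__ = [
    "top_markers",
    "score_cells",
    "assign_labels",
    "subsample_per_group",
    "mapping_table",
]


def top_markers(
    deg_tables: dict[str, pd.DataFrame], n_top: int = 50
) -> dict[str, pd.DataFrame]:
    """First ``n_top`` rows of each reference type's DEG table.

    Tables are assumed sorted by descending log2fc (the find_markers
    contract).  Types with fewer than ``n_top`` significant genes keep what
    they have (with a warning); empty tables are dropped from scoring.
    """
    out: dict[str, pd.DataFrame] = {}
    for ref_type, table in deg_tables.items():
        if len(table) == 0:
            warnings.warn(f"no markers for reference type {ref_type!r}; excluded")
            out[ref_type] = table.copy()
            continue
        if len(table) < n_top:
            warnings.warn(
                f"only {len(table)} markers for {ref_type!r} (requested {n_top})"
            )
        sub = table.head(n_top).copy()
        if sub["gene"].duplicated().any():
            raise ValueError(f"duplicate genes in marker set for {ref_type!r}")
        out[ref_type] = sub
    return out


def score_cells(
    query: NormalizedMatrix,
    marker_sets: dict[str, pd.DataFrame],
    use_zscore: bool = False,
) -> pd.DataFrame:
    """Per-cell similarity scores: mean marker expression per reference type.

    Scores are computed on log-normalized values by default; with
    ``use_zscore`` markers are first z-scored across query cells (population
    SD, constant genes contribute 0).  Markers absent from the query gene
    universe are dropped per type (the mean runs over the genes actually
    used); types with no usable marker are excluded.  Returns cells x types
    DataFrame with a ``usable_markers`` attribute recording how many genes
    backed each column.
    """
    scores: dict[str, np.ndarray] = {}
    usable: dict[str, int] = {}
    for ref_type, table in marker_sets.items():
        genes = [g for g in table["gene"] if g in query.genes]
        if not genes:
            if len(table):
                warnings.warn(
                    f"no marker of {ref_type!r} present in the query; excluded"
                )
            continue
        idx = query.genes.get_indexer(pd.Index(genes))
        sub = np.asarray(query.values[idx, :].todense(), dtype=float)
        if use_zscore:
            mu = sub.mean(axis=1, keepdims=True)
            sd = sub.std(axis=1, keepdims=True)
            sub = np.divide(sub - mu, sd, out=np.zeros_like(sub), where=sd > 0)
        scores[ref_type] = sub.mean(axis=0)
        usable[ref_type] = len(genes)
    if not scores:
        raise ValueError("no reference type has any usable marker in the query")
    df = pd.DataFrame(scores, index=query.cells)
    df.attrs["usable_markers"] = usable
    df.attrs["expression_space"] = "z-score" if use_zscore else "log-normalized"
    return df


def assign_labels(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign each query cell to its best-scoring reference type.

    Exact ties go to the first declared reference type (column order).
    Returns a DataFrame with ``assigned``, ``best_score`` and ``margin``
    (best minus runner-up; 0 when only one type is scored).
    """
    if scores.shape[1] == 0:
        raise ValueError("no scored reference types")
    vals = scores.to_numpy()
    best_idx = np.argmax(vals, axis=1)  # argmax takes the first maximum: tie rule
    best = vals[np.arange(len(scores)), best_idx]
    if scores.shape[1] > 1:
        part = np.partition(vals, -2, axis=1)
        runner = part[:, -2]
        margin = best - runner
    else:
        margin = np.zeros(len(scores))
    return pd.DataFrame(
        {
            "assigned": scores.columns[best_idx],
            "best_score": best,
            "margin": margin,
        },
        index=scores.index,
    )


def subsample_per_group(
    cells, group_labels: pd.Series, fraction: float, seed: int = 0
) -> pd.Index:
    """Sample floor(fraction x group size) cells per group, minimum 1.

    Sampling is without replacement and deterministic given the seed; the
    returned index preserves the input cell order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    cells = pd.Index(cells)
    if len(cells) == 0:
        return cells
    group_labels = group_labels.reindex(cells)
    if group_labels.isna().any():
        raise ValueError("group labels missing for some cells")
    rng = np.random.default_rng(seed)
    chosen: list = []
    for group in pd.unique(group_labels):
        members = cells[(group_labels == group).to_numpy()]
        k = max(int(np.floor(fraction * len(members))), 1)
        pick = rng.choice(len(members), size=k, replace=False)
        chosen.extend(members[np.sort(pick)])
    chosen_set = set(chosen)
    return cells[[c in chosen_set for c in cells]]


def mapping_table(assignment: pd.DataFrame, query_labels: pd.Series) -> pd.DataFrame:
    """Sankey-style flow table: counts and fractions per (query, reference) pair.

    Fractions are within each query subpopulation; zero-count pairs are
    omitted.
    """
    query_labels = query_labels.reindex(assignment.index)
    if query_labels.isna().any():
        raise ValueError("query labels missing for some assigned cells")
    df = pd.DataFrame(
        {
            "query_subpopulation": query_labels.to_numpy(),
            "reference_subpopulation": assignment["assigned"].to_numpy(),
        }
    )
    counts = (
        df.groupby(["query_subpopulation", "reference_subpopulation"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    totals = counts.groupby("query_subpopulation")["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    return counts
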