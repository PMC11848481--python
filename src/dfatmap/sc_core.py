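"""Quality control, normalization, feature selection and clustering.

The stages mirror the standard droplet snRNA-seq preprocessing recipe:
per-cell QC gates, LogNormalize (counts / cell total x 10,000, then log1p),
variance-stabilizing HVG selection, per-gene z-scoring, and a seeded
PCA + k-means clustering utility for synthetic workflows.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import CountMatrix, NormalizedMatrix, QCThresholds, ScaledMatrix

__all__ = [
    "compute_qc_metrics",
    "filter_cells",
    "log_normalize",
    "select_hvgs",
    "scale_data",
    "embed_and_cluster",
]


def compute_qc_metrics(m: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics.

    Returns a DataFrame indexed by cell id with columns ``n_features`` (genes
    with count > 0), ``n_umi`` (column sum), ``pct_mito`` (percent of total
    counts on mitochondrial genes; 0 for an empty cell) and
    ``n_nuclear_features``.
    """
    counts = m.counts.tocsc()
    n_umi = np.asarray(counts.sum(axis=0)).ravel()
    nonzero = counts.copy()
    nonzero.data = (nonzero.data > 0).astype(np.int64)
    n_features = np.asarray(nonzero.sum(axis=0)).ravel()

    mito_mask = m.gene_flags["mito"].to_numpy()
    nuclear_mask = m.gene_flags["nuclear"].to_numpy()
    mito_umi = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()
    n_nuclear = np.asarray(nonzero[nuclear_mask, :].sum(axis=0)).ravel()

    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(n_umi > 0, 100.0 * mito_umi / np.maximum(n_umi, 1), 0.0)

    return pd.DataFrame(
        {
            "n_features": n_features.astype(int),
            "n_umi": n_umi.astype(int),
            "pct_mito": pct_mito,
            "n_nuclear_features": n_nuclear.astype(int),
        },
        index=m.cells,
    )


def qc_pass_mask(metrics: pd.DataFrame, t: QCThresholds) -> pd.Series:
    """Boolean per-cell pass/fail under thresholds ``t``.

    Feature and UMI ranges are inclusive; the mitochondrial gate is strict
    (``pct_mito < max_pct_mito``).
    """
    return (
        metrics["n_features"].between(t.min_features, t.max_features)
        & metrics["n_umi"].between(t.min_umi, t.max_umi)
        & (metrics["pct_mito"] < t.max_pct_mito)
        & (metrics["n_nuclear_features"] >= t.min_nuclear_features)
    )


def filter_cells(
    m: CountMatrix, metrics: pd.DataFrame, t: QCThresholds | None = None
) -> CountMatrix:
    """Drop cells failing QC; cell order and the gene axis are unchanged."""
    if t is None:
        t = QCThresholds()
    if not metrics.index.equals(m.cells):
        raise ValueError("QC metrics index does not match matrix cells")
    keep = qc_pass_mask(metrics, t)
    return m.subset_cells(m.cells[keep.to_numpy()])


def log_normalize(m: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """LogNormalize: value = log(1 + count / cell_total * scale_factor).

    Natural logarithm; zero counts map to zero exactly, so the sparsity
    pattern is preserved.  Cells with zero total counts are rejected.
    """
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = list(m.cells[totals == 0][:5])
        raise ValueError(
            f"cells with zero total counts, e.g. {bad}; run filter_cells first"
        )
    x = m.counts.tocsc().astype(float)
    # scale each column by scale_factor / total, then log1p on stored entries
    x = x @ sp.diags(scale_factor / totals)
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        genes=m.genes, cells=m.cells, values=x.tocsr(), scale_factor=scale_factor
    )


def _loess_quadratic(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Local degree-2 polynomial fit of y on x with tricube weights.

    Plain O(n^2) implementation, adequate for the gene counts this package
    works with (<= a few 10^4 genes).
    """
    n = len(x)
    k = min(max(int(np.ceil(span * n)), 3), n)
    fitted = np.empty(n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for i in range(n):
        xi = x[i]
        d = np.abs(xs - xi)
        # k nearest neighbours in x
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = ys[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        deg = min(2, max(int((w > 0).sum()) - 1, 0))
        if deg == 0:
            fitted[i] = np.average(ys[idx], weights=np.maximum(w, 1e-12))
            continue
        try:
            coef = np.polyfit(xs[idx], ys[idx], deg=deg, w=np.sqrt(w))
            fitted[i] = np.polyval(coef, xi)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate window
            fitted[i] = np.average(ys[idx], weights=w)
    return fitted


def select_hvgs(m: CountMatrix, n_top: int, span: float = 0.3) -> list[str]:
    """Rank genes by variance-stabilized standardized variance.

    A degree-2 local regression of log10(variance) on log10(mean) over genes
    gives each gene an expected SD; raw counts are standardized by it, clipped
    at sqrt(n_cells), and genes are ranked by the variance of the clipped
    standardized values.  Ties and all-constant genes fall back to a stable
    order by gene id.
    """
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells for variance estimation")
    if n_top > m.n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds gene count {m.n_genes}; returning all genes"
        )
        n_top = m.n_genes

    x = m.counts.tocsr().astype(float)
    n = m.n_cells
    mean = np.asarray(x.mean(axis=1)).ravel()
    sq = x.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n / (n - 1)

    std_var = np.zeros(m.n_genes)
    usable = (var > 0) & (mean > 0)
    if usable.any():
        lx = np.log10(mean[usable])
        ly = np.log10(var[usable])
        fitted_sd = np.sqrt(10 ** _loess_quadratic(lx, ly, span))
        clip = np.sqrt(n)
        rows = np.flatnonzero(usable)
        for pos, g in enumerate(rows):
            row = x.getrow(g)
            z_nz = (row.data - mean[g]) / fitted_sd[pos]
            z0 = (0.0 - mean[g]) / fitted_sd[pos]
            z_nz = np.minimum(z_nz, clip)
            z0 = min(z0, clip)
            n_zero = n - row.nnz
            # variance of clipped standardized values around 0 (convention of
            # the VST method): sum(z^2) / (n - 1)
            std_var[g] = (np.sum(z_nz**2) + n_zero * z0**2) / (n - 1)

    order = sorted(range(m.n_genes), key=lambda g: (-std_var[g], m.genes[g]))
    return [m.genes[g] for g in order[:n_top]]


def scale_data(
    nm: NormalizedMatrix, genes: list[str] | None = None, clip: float | None = None
) -> ScaledMatrix:
    """Per-gene z-scores across cells (population SD convention).

    Constant genes become all-zero rows; optional symmetric clipping at
    ``clip`` is applied after standardization.
    """
    if genes is None:
        genes = list(nm.genes)
    if len(genes) == 0:
        raise ValueError("empty gene list")
    idx = nm.genes.get_indexer(pd.Index(genes))
    if (idx < 0).any():
        missing = [g for g, i in zip(genes, idx) if i < 0][:5]
        raise KeyError(f"genes absent from matrix, e.g. {missing}")
    dense = np.asarray(nm.values[idx, :].todense(), dtype=float)
    mu = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, keepdims=True)  # population SD
    out = np.zeros_like(dense)
    nonconst = sd.ravel() > 0
    out[nonconst] = (dense[nonconst] - mu[nonconst]) / sd[nonconst]
    if clip is not None:
        out = np.clip(out, -clip, clip)
    return ScaledMatrix(
        genes=pd.Index(genes), cells=nm.cells, values=out, clip_value=clip
    )


def embed_and_cluster(
    sm: ScaledMatrix, n_components: int = 10, k: int = 2, seed: int = 0
) -> pd.Series:
    """PCA embedding followed by seeded k-means; labels in 0..k-1 per cell.

    A deterministic stand-in for graph clustering, used in synthetic
    workflows when truth labels are withheld.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > sm.values.shape[1]:
        raise ValueError("k exceeds the number of cells")
    x = sm.values.T  # cells x genes
    n_components = min(n_components, min(x.shape) - 1) or 1
    emb = PCA(n_components=n_components, random_state=seed).fit_transform(x)
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb)
    return pd.Series(labels, index=sm.cells, name="cluster")
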