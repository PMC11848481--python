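"""Core in-memory containers for the single-cell side of the pipeline.

The transcriptomic substrate is a genes x cells sparse UMI count matrix with
per-gene flags (mitochondrial / nuclear) and per-cell metadata.  Downstream
stages carry the same axes through normalization and scaling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "ScaledMatrix",
    "QCThresholds",
    "SMARTSEQ3_QC",
]


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} ids, e.g. {dup}")


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI counts with gene and cell annotations.

    Parameters
    ----------
    genes, cells
        Unique ordered identifiers for the two axes.
    counts
        Non-negative integer sparse matrix, shape ``(len(genes), len(cells))``.
    cell_meta
        Optional per-cell annotations (sample, condition, cluster labels ...),
        indexed by cell id.
    gene_flags
        Boolean per-gene flags indexed by gene id; columns ``mito`` and
        ``nuclear`` are created (all-False / all-True) when absent.
    """

    genes: pd.Index
    cells: pd.Index
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    gene_flags: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "cell")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise ValueError("counts must be integral")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cells)
        else:
            self.cell_meta = self.cell_meta.reindex(self.cells)
        if self.gene_flags is None:
            self.gene_flags = pd.DataFrame(index=self.genes)
        else:
            self.gene_flags = self.gene_flags.reindex(self.genes)
        if "mito" not in self.gene_flags:
            self.gene_flags["mito"] = False
        if "nuclear" not in self.gene_flags:
            self.gene_flags["nuclear"] = ~self.gene_flags["mito"]
        self.gene_flags = self.gene_flags.fillna(False).astype(bool)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_cells(self, cell_ids) -> "CountMatrix":
        """Return a new matrix restricted to ``cell_ids`` (order preserved)."""
        idx = self.cells.get_indexer(pd.Index(cell_ids))
        if (idx < 0).any():
            missing = list(pd.Index(cell_ids)[idx < 0][:5])
            raise KeyError(f"unknown cell ids, e.g. {missing}")
        return CountMatrix(
            genes=self.genes,
            cells=self.cells[idx],
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta.iloc[idx],
            gene_flags=self.gene_flags,
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression on the same axes as its source counts.

    ``values[g, c] = log(1 + count[g, c] / total[c] * scale_factor)`` with the
    natural logarithm; zeros stay exactly zero so the sparsity pattern of the
    counts is preserved.
    """

    genes: pd.Index
    cells: pd.Index
    values: sp.csr_matrix
    scale_factor: float = 10_000.0
    log_base: str = "e"

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape does not match axes")
        if self.values.nnz and not np.all(np.isfinite(self.values.data)):
            raise ValueError("normalized values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class ScaledMatrix:
    """Per-gene z-scored expression (dense), genes x cells.

    Each row has mean 0 and population SD 1 (constant genes are all-zero);
    optional symmetric clipping is applied after standardization.
    """

    genes: pd.Index
    cells: pd.Index
    values: np.ndarray
    clip_value: float | None = None

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape does not match axes")


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC gates.

    Defaults follow the snRNA-seq convention used throughout this package:
    200-7500 detected genes and 500-75,000 UMIs (both ranges inclusive),
    mitochondrial reads strictly below 10% of total, and at least 10 detected
    nuclear genes.
    """

    min_features: int = 200
    max_features: int = 7_500
    min_umi: int = 500
    max_umi: int = 75_000
    max_pct_mito: float = 10.0
    min_nuclear_features: int = 10

    def __post_init__(self) -> None:
        if self.min_features > self.max_features:
            raise ValueError("min_features > max_features")
        if self.min_umi > self.max_umi:
            raise ValueError("min_umi > max_umi")


#: Smart-seq3 preset: 100-6000 detected genes, mito < 10%, no UMI gate.
SMARTSEQ3_QC = QCThresholds(
    min_features=100,
    max_features=6_000,
    min_umi=0,
    max_umi=np.iinfo(np.int64).max,
    max_pct_mito=10.0,
    min_nuclear_features=0,
)
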