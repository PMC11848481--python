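"""Readers and writers for the plain-text interchange formats.

Count matrices travel as MatrixMarket MTX (genes x cells) plus features.tsv
and barcodes.tsv; methylomes as bedGraph (with an optional 5th coverage
column); TSS annotations as BED6 (name = gene id, 1-based TSS recovered from
the strand-aware interval); truth tables and result tables as TSV.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix
from .methylation import MethylationTrack

__all__ = [
    "write_count_matrix",
    "read_count_matrix",
    "write_bedgraph",
    "write_tss_bed",
    "read_tss_bed",
]


def write_count_matrix(m: CountMatrix, out_dir) -> dict[str, Path]:
    """Write matrix.mtx + features.tsv + barcodes.tsv (+ cell_meta.tsv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mtx = out_dir / "matrix.mtx"
    scipy.io.mmwrite(str(mtx), sp.coo_matrix(m.counts), field="integer")
    feats = pd.DataFrame(
        {
            "gene": m.genes,
            "mito": m.gene_flags["mito"].astype(int).to_numpy(),
            "nuclear": m.gene_flags["nuclear"].astype(int).to_numpy(),
        }
    )
    feats.to_csv(out_dir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(m.cells).to_csv(
        out_dir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    paths = {
        "matrix": mtx,
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    if len(m.cell_meta.columns):
        meta = out_dir / "cell_meta.tsv"
        m.cell_meta.to_csv(meta, sep="\t", index_label="cell")
        paths["cell_meta"] = meta
    return paths


def read_count_matrix(in_dir) -> CountMatrix:
    """Read the MTX + features + barcodes triple written by write_count_matrix."""
    in_dir = Path(in_dir)
    counts = sp.csr_matrix(scipy.io.mmread(str(in_dir / "matrix.mtx")))
    feats = pd.read_csv(
        in_dir / "features.tsv", sep="\t", header=None,
        names=["gene", "mito", "nuclear"],
    )
    barcodes = pd.read_csv(
        in_dir / "barcodes.tsv", sep="\t", header=None, names=["cell"]
    )["cell"]
    gene_flags = pd.DataFrame(
        {"mito": feats["mito"].astype(bool), "nuclear": feats["nuclear"].astype(bool)}
    )
    gene_flags.index = pd.Index(feats["gene"])
    meta_path = in_dir / "cell_meta.tsv"
    cell_meta = None
    if meta_path.exists():
        cell_meta = pd.read_csv(meta_path, sep="\t", index_col="cell")
    return CountMatrix(
        genes=pd.Index(feats["gene"]),
        cells=pd.Index(barcodes),
        counts=counts,
        cell_meta=cell_meta,
        gene_flags=gene_flags,
    )


def write_bedgraph(track: MethylationTrack, path) -> Path:
    """Write a track as 4- or 5-column bedGraph (levels to 6 decimals)."""
    path = Path(path)
    rec = track.records.copy()
    rec["level"] = rec["level"].map(lambda v: f"{v:.6f}")
    cols = ["chrom", "start", "end", "level"]
    if "coverage" in rec.columns:
        cols.append("coverage")
    rec[cols].to_csv(path, sep="\t", index=False, header=False)
    return path


def write_tss_bed(annot: pd.DataFrame, path) -> Path:
    """Write a TSS annotation as BED6 (1-bp interval at the TSS).

    The BED interval is [tss-1, tss) in 0-based half-open coordinates; the
    name column carries the gene id and column 6 the strand.
    """
    path = Path(path)
    bed = pd.DataFrame(
        {
            "chrom": annot["chrom"],
            "start": annot["tss"] - 1,
            "end": annot["tss"],
            "name": annot["gene"],
            "score": 0,
            "strand": annot["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
    return path


def read_tss_bed(path) -> pd.DataFrame:
    """Read a BED6 TSS annotation back into (gene, chrom, tss, strand)."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "gene": bed["name"],
            "chrom": bed["chrom"],
            "tss": bed["start"] + 1,
            "strand": bed["strand"],
        }
    )
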