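"""TSS-anchored methylation profiles and diet-reversibility patterns.

Per-CpG methylation fractions (bedGraph tracks, one per diet condition) are
summarized around transcription start sites in two ways: a genes x bins
profile matrix (default +/-2 kb, 10-bp bins, oriented 5'->3' along the gene)
for composite plots, and a per-gene mean within +/-1 kb used for pattern
analysis.  Per-gene (CD, HFD, HFD-CD) triples are clustered with k-means
after per-gene centering, and each cluster centroid is labelled:

* Pattern 1 - the HFD shift is reversed by switching back to CD,
* Pattern 2 - the HFD shift persists after the switch,
* Pattern 3 - the change is specific to the switched (HFD-CD) group,

with genes inheriting their cluster's label.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "MethylationTrack",
    "PatternParams",
    "read_methylation_track",
    "tss_profile_matrix",
    "composite_profile",
    "gene_tss_methylation",
    "gene_methylation_summary",
    "cluster_patterns",
    "classify_patterns",
    "gene_set_methylation",
    "PATTERN_LABELS",
]

PATTERN_LABELS = ("Pattern1", "Pattern2", "Pattern3", "unclassified")


@dataclass
class MethylationTrack:
    """Sorted, non-overlapping per-CpG methylation fractions for one condition.

    ``records`` has columns chrom, start (0-based), end (half-open), level
    (fraction in [0, 1]) and optionally coverage.
    """

    condition: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["chrom", "start", "end", "level"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"track records missing columns {missing}")
        rec = self.records.sort_values(["chrom", "start"], kind="mergesort")
        rec = rec.reset_index(drop=True)
        if (rec["start"] >= rec["end"]).any():
            bad = rec.index[(rec["start"] >= rec["end"]).to_numpy()][0]
            raise ValueError(f"record {bad}: start >= end")
        if ((rec["level"] < 0) | (rec["level"] > 1)).any():
            raise ValueError("levels must lie in [0, 1]")
        same_chrom = rec["chrom"].shift(-1) == rec["chrom"]
        overlap = same_chrom & (rec["end"] > rec["start"].shift(-1))
        if overlap.any():
            bad = rec.index[overlap.to_numpy()][0]
            raise ValueError(f"overlapping records near row {bad}")
        self.records = rec


@dataclass(frozen=True)
class PatternParams:
    """k-means and centroid-rule parameters for pattern calling.

    ``delta`` is the minimal meaningful methylation difference (fraction
    units); ``tau`` is the tolerated residual after the diet switch as a
    fraction of the HFD effect.
    """

    k: int = 6
    seed: int = 0
    delta: float = 0.1
    tau: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")


def read_methylation_track(path, condition: str) -> MethylationTrack:
    """Read a bedGraph file (4 or 5 columns; column 5 = coverage).

    Levels are fractions; a 0-100 percent dialect is auto-detected (any value
    above 1) and divided by 100 with a logged notice.  Track definition lines
    starting with ``track`` or ``#`` are skipped.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            try:
                rec = [parts[0], int(parts[1]), int(parts[2]), float(parts[3])]
                cov = int(parts[4]) if len(parts) > 4 else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record ({exc})") from None
            rows.append(rec + [cov])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "level", "coverage"])
    if df["coverage"].isna().all():
        df = df.drop(columns="coverage")
    if len(df) and df["level"].max() > 1:
        warnings.warn(f"{path}: levels look like percentages (max > 1); dividing by 100")
        df["level"] = df["level"] / 100.0
    try:
        return MethylationTrack(condition=condition, records=df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


@dataclass
class ProfileMatrix:
    """Genes x bins methylation profile, oriented 5'->3' along each gene."""

    values: pd.DataFrame  # index genes, columns bin index; NaN = no CpG
    flank: int
    bin_size: int

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def _check_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    req = ["gene", "chrom", "tss", "strand"]
    missing = [c for c in req if c not in annot.columns]
    if missing:
        raise ValueError(f"TSS annotation missing columns {missing}")
    if annot["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in TSS annotation")
    if not annot["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return annot


def _window_stats(track: MethylationTrack, annot: pd.DataFrame, flank: int):
    """Yield (gene, strand, starts, ends, levels) for records overlapping
    each gene's [tss0 - flank, tss0 + flank) window (tss0 = 0-based TSS)."""
    by_chrom = {
        chrom: sub.reset_index(drop=True)
        for chrom, sub in track.records.groupby("chrom", sort=False)
    }
    for row in annot.itertuples(index=False):
        tss0 = row.tss - 1
        w0, w1 = tss0 - flank, tss0 + flank
        sub = by_chrom.get(row.chrom)
        if sub is None:
            warnings.warn(f"gene {row.gene}: chromosome {row.chrom} absent from track")
            yield row.gene, row.strand, np.empty(0, int), np.empty(0, int), np.empty(0)
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = np.searchsorted(ends, w0, side="right")
        hi = np.searchsorted(starts, w1, side="left")
        sel = slice(lo, hi)
        yield (
            row.gene,
            row.strand,
            np.maximum(starts[sel], w0) - w0,
            np.minimum(ends[sel], w1) - w0,
            sub["level"].to_numpy()[sel],
        )


def tss_profile_matrix(
    track: MethylationTrack,
    annot: pd.DataFrame,
    flank: int = 2000,
    bin_size: int = 10,
) -> ProfileMatrix:
    """Genes x bins profile over [tss - flank, tss + flank).

    A bin's value is the unweighted mean of the levels of CpG records
    overlapping it; empty bins are NaN.  Rows of minus-strand genes are
    reversed so bin 0 is always ``flank`` bp upstream in gene orientation.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    annot = _check_annotation(annot)
    n_bins = 2 * flank // bin_size
    out = np.full((len(annot), n_bins), np.nan)
    for gi, (gene, strand, s, e, lev) in enumerate(
        _window_stats(track, annot, flank)
    ):
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        for j in range(len(s)):
            b0 = s[j] // bin_size
            b1 = (e[j] - 1) // bin_size
            sums[b0 : b1 + 1] += lev[j]
            counts[b0 : b1 + 1] += 1
        row = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        if strand == "-":
            row = row[::-1]
        out[gi] = row
    return ProfileMatrix(
        values=pd.DataFrame(out, index=pd.Index(annot["gene"], name="gene")),
        flank=flank,
        bin_size=bin_size,
    )


def composite_profile(profile: ProfileMatrix) -> pd.DataFrame:
    """Per-bin mean, standard error and gene count over non-missing entries."""
    if profile.values.shape[0] < 1:
        raise ValueError("profile matrix has no genes")
    vals = profile.values.to_numpy()
    n = np.sum(~np.isnan(vals), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    pos = (np.arange(profile.n_bins) + 0.5) * profile.bin_size - profile.flank
    return pd.DataFrame(
        {"position": pos, "mean": mean, "se": se, "n_genes": n},
        index=profile.values.columns,
    )


def gene_tss_methylation(
    track: MethylationTrack, annot: pd.DataFrame, flank: int = 1000
) -> pd.Series:
    """Per-gene unweighted mean CpG level within [tss - flank, tss + flank).

    Genes with no covered CpG are NaN (missing), never zero.
    """
    annot = _check_annotation(annot)
    vals = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # absent-chromosome notices
        for gene, _strand, _s, _e, lev in _window_stats(track, annot, flank):
            vals[gene] = float(np.mean(lev)) if len(lev) else np.nan
    return pd.Series(vals, name=track.condition)


def gene_methylation_summary(
    tracks: list[MethylationTrack], annot: pd.DataFrame, flank: int = 1000
) -> pd.DataFrame:
    """Genes x conditions matrix of +/-flank TSS methylation means."""
    cols = [gene_tss_methylation(t, annot, flank=flank) for t in tracks]
    return pd.concat(cols, axis=1)


def cluster_patterns(
    summary: pd.DataFrame, params: PatternParams | None = None
) -> pd.Series:
    """Seeded k-means over per-gene centered condition triples.

    ``summary`` must have exactly 3 condition columns in (CD, HFD, HFD-CD)
    order.  Genes with any missing condition are excluded (reported via a
    warning).  Per-gene centering makes clusters reflect the shape of the
    diet response rather than the absolute methylation level.
    """
    if params is None:
        params = PatternParams()
    if summary.shape[1] != 3:
        raise ValueError("summary must have exactly 3 condition columns")
    complete = summary.dropna()
    n_excluded = len(summary) - len(complete)
    if n_excluded:
        warnings.warn(f"{n_excluded} genes with missing conditions excluded")
    if len(complete) < params.k:
        raise ValueError(f"only {len(complete)} complete genes for k={params.k}")
    x = complete.to_numpy()
    x = x - x.mean(axis=1, keepdims=True)
    km = KMeans(n_clusters=params.k, n_init=10, random_state=params.seed)
    labels = km.fit_predict(x)
    return pd.Series(labels, index=complete.index, name="cluster")


def _label_centroid(a: float, b: float, c: float, params: PatternParams) -> str:
    """Pattern label for a (CD, HFD, HFD-CD) centroid."""
    d = b - a  # HFD effect
    r = c - a  # residual after switching back to CD
    if abs(d) > params.delta and abs(r) <= params.tau * abs(d):
        return "Pattern1"
    if abs(d) > params.delta and abs(c - b) <= params.tau * abs(d):
        return "Pattern2"
    if abs(d) <= params.delta and abs(r) > params.delta:
        return "Pattern3"
    return "unclassified"


def classify_patterns(
    summary: pd.DataFrame, clusters: pd.Series, params: PatternParams | None = None
) -> pd.DataFrame:
    """Label each k-means cluster centroid and propagate to its genes.

    Returns a DataFrame indexed by gene with columns ``cluster`` and
    ``pattern`` (Pattern1 / Pattern2 / Pattern3 / unclassified).
    """
    if params is None:
        params = PatternParams()
    sub = summary.loc[clusters.index]
    cluster_labels = {}
    for cid, members in sub.groupby(clusters):
        a, b, c = members.mean(axis=0).to_numpy()
        cluster_labels[cid] = _label_centroid(a, b, c, params)
    return pd.DataFrame(
        {
            "cluster": clusters,
            "pattern": clusters.map(cluster_labels),
        }
    )


def gene_set_methylation(
    summary: pd.DataFrame, gene_list
) -> tuple[pd.DataFrame, int]:
    """Summary rows restricted to a gene list (e.g. a pathway's genes).

    Returns the per-condition value matrix for the list genes found in the
    summary and the number found; raises if none overlap.
    """
    gene_list = pd.Index(gene_list)
    if len(gene_list) == 0:
        raise ValueError("gene list is empty")
    found = gene_list[gene_list.isin(summary.index)]
    if len(found) == 0:
        raise ValueError("no gene of the list is present in the summary")
    found = found.rename(summary.index.name)
    return summary.loc[found], len(found)
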